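"""Shared brute-force oracles and helpers used by more than one test module."""

import numpy as np


def matches_printed(value, printed, decimals=2):
    """True when ``value`` rounds to the printed figure at the printed
    precision (half-up, as report tables round)."""
    return abs(value - printed) <= 0.5 * 10.0**(-decimals) + 1e-12


def brute_erode(mask, footprint):
    h, w = mask.shape
    offs = [(i - 1, j - 1) for i in range(3) for j in range(3)
            if footprint[i, j]]
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            out[y, x] = all(
                0 <= y + dy < h and 0 <= x + dx < w and mask[y + dy, x + dx]
                for dy, dx in offs)
    return out


def brute_dilate(mask, footprint):
    h, w = mask.shape
    offs = [(i - 1, j - 1) for i in range(3) for j in range(3)
            if footprint[i, j]]
    out = np.zeros_like(mask, dtype=bool)
    for y, x in np.argwhere(mask):
        for dy, dx in offs:
            if 0 <= y + dy < h and 0 <= x + dx < w:
                out[y + dy, x + dx] = True
    return out
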