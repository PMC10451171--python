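"""Agreement and error statistics for CSAmin localisation.

Cohen's kappa on the segment contingency table, Bland-Altman limits of
agreement on paired heights, intraclass correlation, paired and two-sample
t-tests, below-threshold error proportions and column summaries.  SD
convention throughout is the sample standard deviation (n-1), matching the
statistics-package defaults the reference analysis used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .csamin import px_to_mm
from .imgio import ContingencyTable, load_table4, load_table5

__all__ = [
    "KappaResult", "BlandAltmanResult", "cohen_kappa", "bland_altman",
    "icc", "paired_t", "two_sample_t", "proportion_below", "column_summary",
    "table5_statistics", "table4_statistics",
]


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    n: int
    n_within: int

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.n_within / self.n


def cohen_kappa(table: ContingencyTable | np.ndarray) -> KappaResult:
    """Unweighted Cohen's kappa from a k x k contingency table."""
    counts = table.counts if isinstance(table, ContingencyTable) \
        else np.asarray(table, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("contingency table must have positive total")
    po = np.trace(counts) / n
    pe = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / n**2)
    if pe >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1, "
                         "kappa undefined")
    return KappaResult(po=float(po), pe=pe, kappa=(po - pe) / (1 - pe),
                       n=int(n))


def bland_altman(a, b) -> BlandAltmanResult:
    """Limits of agreement for paired measurements ``a`` and ``b``.

    Differences are ``a - b``; limits are mean +/- 1.96 sample SD, and a
    point counts as within the limits inclusively.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D arrays of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = m - 1.96 * sd, m + 1.96 * sd
    within = int(np.count_nonzero(np.abs(d - m) <= 1.96 * sd))
    return BlandAltmanResult(mean_diff=m, sd_diff=sd, lower_limit=lo,
                             upper_limit=hi, n=len(d), n_within=within)


def icc(ratings: np.ndarray, form: str = "ICC2") -> float:
    """Intraclass correlation for a subjects x raters matrix.

    Default form is the single-measure absolute-agreement coefficient of
    the two-way model (``ICC2``); ``ICC1``/``ICC3`` select the one-way and
    consistency forms.
    """
    import pingouin as pg

    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("ratings must be (>=3 subjects) x (>=2 raters)")
    if np.ptp(m) == 0:
        raise ValueError("constant ratings: ICC undefined")
    ns, nr = m.shape
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(ns), nr),
        "rater": np.tile(np.arange(nr), ns),
        "score": m.ravel(),
    })
    res = pg.intraclass_corr(data=df, targets="subject", raters="rater",
                             ratings="score")
    aliases = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
               "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)"}
    label = aliases.get(form, form)
    row = res[res["Type"] == label]
    if row.empty:
        raise ValueError(f"unknown ICC form {form!r}")
    return float(row["ICC"].iloc[0])


def paired_t(a, b) -> tuple[float, int, float]:
    """Paired t-test; returns (t, dof, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired t-test needs two equal-length arrays, n>=2")
    if np.all(a == b):
        # zero difference with zero variance: no evidence of any effect
        return 0.0, len(a) - 1, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Two-sample t-test with pooled variance; returns (t, dof, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two-sample t-test needs n>=2 per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), len(a) + len(b) - 2, float(res.pvalue)


def proportion_below(values, threshold: float) -> tuple[int, float]:
    """Count and percentage of values strictly below ``threshold``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    count = int(np.count_nonzero(v < threshold))
    return count, 100.0 * count / v.size


def column_summary(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) SD."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    return float(v.mean()), float(v.std(ddof=1))


# ---------------------------------------------------------------------------
# Fixture-driven reproduction reports


def table5_statistics(pixel_spacing_mm: float | None = None) -> dict:
    """Recompute every summary statistic of the packaged height/error table.

    mm errors are derived from the pixel errors through the pixel spacing
    (default 200/910 mm/px) rather than read from the printed mm columns.
    """
    from .imgio import PIXEL_SPACING_MM
    sp = PIXEL_SPACING_MM if pixel_spacing_mm is None else pixel_spacing_mm
    recs = load_table5()
    h_t = np.array([r.h_t for r in recs], dtype=float)
    h1 = np.array([r.h1 for r in recs], dtype=float)
    h2 = np.array([r.h2 for r in recs], dtype=float)
    l1_px = np.abs(h1 - h_t)
    l2_px = np.abs(h2 - h_t)
    l1_mm = l1_px * sp
    l2_mm = l2_px * sp
    ba1 = bland_altman(h_t, h1)
    ba2 = bland_altman(h_t, h2)
    n1, p1 = proportion_below(l1_mm, 3.0)
    n2, p2 = proportion_below(l2_mm, 3.0)
    t1 = paired_t(h_t, h1)
    t2 = paired_t(h_t, h2)
    tl = two_sample_t(l1_px, l2_px)
    out = {
        "n": len(recs),
        "mean_h_t": column_summary(h_t),
        "mean_h1": column_summary(h1),
        "mean_h2": column_summary(h2),
        "l1_px": column_summary(l1_px),
        "l2_px": column_summary(l2_px),
        "l1_mm": column_summary(l1_mm),
        "l2_mm": column_summary(l2_mm),
        "l1_range_mm": (float(l1_mm.min()), float(l1_mm.max())),
        "l2_range_mm": (float(l2_mm.min()), float(l2_mm.max())),
        "bland_altman_h1": ba1,
        "bland_altman_h2": ba2,
        "below_3mm_l1": (n1, p1),
        "below_3mm_l2": (n2, p2),
        "paired_t_h1": t1,
        "paired_t_h2": t2,
        "two_sample_t_l1_l2": tl,
    }
    return out


def table4_statistics() -> dict:
    """Kappa and segment distribution from the packaged contingency table."""
    table = load_table4()
    k = cohen_kappa(table)
    ai_rp = int(table.counts[0].sum())
    return {
        "table": table,
        "kappa": k,
        "ai_retropalatal": ai_rp,
        "ai_retropalatal_pct": 100.0 * ai_rp / table.total,
        "disagreements": int(table.total - np.trace(table.counts)),
    }
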