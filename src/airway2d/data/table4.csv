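ai_segment,manual_retropalatal,manual_retroglossal
retropalatal,27,0
retroglossal,1,12
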