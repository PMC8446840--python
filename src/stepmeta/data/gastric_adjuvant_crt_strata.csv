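label,estimate,ci_lower,ci_upper,measure_kind,ci_level
All studies,1.264,0.997,1.603,ratio,0.95
Balanced studies,1.417,1.171,1.715,ratio,0.95
Randomized studies,1.440,1.110,1.867,ratio,0.95
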