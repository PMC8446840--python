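label,estimate,ci_lower,ci_upper,measure_kind,ci_level
All studies,3.039,2.272,4.064,ratio,0.95
Balanced studies,2.560,1.791,3.659,ratio,0.95
Randomized studies,1.406,1.015,1.949,ratio,0.95
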