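metric,FB,EB,FD,ED,RR
sensitivity,93.40,90.47,85.18,73.83,82.13
specificity,97.47,98.43,94.15,95.31,95.86
accuracy,96.66,96.84,92.35,91.02,93.10
efficiency,95.84,95.24,90.56,86.72,90.36
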