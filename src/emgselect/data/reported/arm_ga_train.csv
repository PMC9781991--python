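metric,FB,EB,FD,ED,RR
sensitivity,93.20,89.57,84.47,72.940,81.75
specificity,97.19,98.39,94.03,95.32,95.59
accuracy,96.38,96.61,92.14,90.81,92.88
efficiency,95.59,94.86,90.22,86.36,90.07
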