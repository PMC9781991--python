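metric,FB,EB,FD,ED,RR
sensitivity,79.88,78.742,68.15,69.72,85.99
specificity,92.56,89.328,94.82,95.31,98.60
accuracy,90.01,87.22,89.5,90.20,96.08
efficiency,87.48,85.097,84.16,85.08,93.562
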