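metric,FB,EB,FD,ED,RR
sensitivity,79.83,78.36,69.70,69.57,86.10
specificity,92.38,89.42,94.77,95.49,98.81
accuracy,89.88,87.21,89.75,90.30,96.27
efficiency,87.36,84.99,84.74,85.12,93.73
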