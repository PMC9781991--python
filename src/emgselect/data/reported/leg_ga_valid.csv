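metric,AP,AT,LP,LT,PD,PI,RR
sensitivity,92.99,89.53,94.71,88.40,83.84,83.94,96.59
specificity,98.4,98.16,98.49,98.677,97.86,97.92,98.75
accuracy,97.67,96.91,97.95,97.23,95.84,95.91,98.44
efficiency,96.37,94.87,97.05,94.77,92.51,92.59,97.93
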