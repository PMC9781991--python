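metric,AP,AT,LP,LT,PD,PI,RR
sensitivity,92.62,89.12,94.48,88.03,83.74,83.98,95.38
specificity,98.40,98.09,98.63,98.58,97.83,97.77,98.61
accuracy,97.56,96.84,98.03,97.02,95.85,95.81,98.15
efficiency,96.19,94.68,97.052,94.54,92.47,92.52,97.38
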