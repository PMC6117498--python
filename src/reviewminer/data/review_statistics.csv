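disease,n_reviews,n_doctors,mean_length
Infertility,71556,3573,444
Infantile pneumonia,21839,2148,435
Infantile diarrhea,711,275,499
Influenza,1796,643,408
Hyperthyroidism,3028,872,383
Diabetes,20849,2627,360
Liver cancer,1679,288,569
Gastric cancer,1053,231,560
Hypertension,205,107,369
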