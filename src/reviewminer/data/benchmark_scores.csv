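disease,precision,recall,f_score
Infertility,0.672,0.738,0.682
Liver cancer,0.942,0.815,0.862
Influenza,0.742,0.795,0.762
Hypertension,0.863,0.958,0.904
Hyperthyroidism,0.947,0.774,0.821
Diabetes,0.883,0.878,0.871
Gastric cancer,0.927,0.704,0.795
Infantile pneumonia,1.000,0.722,0.820
Infantile diarrhea,0.967,0.745,0.826
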