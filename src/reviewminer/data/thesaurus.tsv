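physician	doctor
doc	doctor
medicine	drug
medication	drug
meds	drug
fee	cost
charge	cost
fever	fever
pyrexia	fever
operation	surgery
courteous	polite
impolite	rude
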