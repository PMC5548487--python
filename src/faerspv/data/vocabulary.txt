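Sexual dysfunction
Myocardial infarction
Diabetes mellitus
Cardiac failure congestive
Gastric ulcer
Hypertension
Gynaecomastia
Depression
Osteoarthritis
Headache
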