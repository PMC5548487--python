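report_id$drug_seq$indication
1000001$1$Depression
1000002$1$Osteoarthritis
1000003$1$Diabetes mellitus
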