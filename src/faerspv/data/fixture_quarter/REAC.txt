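report_id$reaction
1000001$Sexual dysfunction
1000002$Myocardial infarction
1000003$Diabetes mellitus
9999999$Headache
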