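report_id$outcome
1000001$OT
1000002$DE
1000002$HO
1000003$HO
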