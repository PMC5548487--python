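report_id$case_id$event_date$receipt_date$occupation$age$age_unit$sex
1000001$500001$2004-03-10$2004-04-01$MD$54$YR$F
1000002$500002$2004-05-02$2004-05-20$LW$61$YR$M
1000003$500003$$2004-06-15$CN$7$DEC$F
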