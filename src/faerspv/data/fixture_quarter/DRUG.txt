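report_id$drug_seq$role$drug_name
1000001$1$PS$fluoxetine hydrochloride
1000001$2$C$ibuprofen
1000002$1$PS$rofecoxib
1000003$1$PS$rosiglitazone maleate
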