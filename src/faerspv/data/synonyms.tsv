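# synonym<TAB>ingredient_key[;ingredient_key...]
fluoxetine	RTHCYVBBDHJXIQ-UHFFFAOYSA-N
fluoxetine hydrochloride	RTHCYVBBDHJXIQ-UHFFFAOYSA-N
prozac	RTHCYVBBDHJXIQ-UHFFFAOYSA-N
ibuprofen	HEFNNWSXXWATRW-UHFFFAOYSA-N
rofecoxib	RZJQGNCSTQAWON-UHFFFAOYSA-N
celecoxib	RZEKVGVHFLEQIL-UHFFFAOYSA-N
rosiglitazone	YASAKCUCGLMORW-UHFFFAOYSA-N
rosiglitazone maleate	YASAKCUCGLMORW-UHFFFAOYSA-N
pioglitazone	HYAFETHFCAUJAY-UHFFFAOYSA-N
methylphenidate	DUGOZIWVEXMGBE-UHFFFAOYSA-N
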