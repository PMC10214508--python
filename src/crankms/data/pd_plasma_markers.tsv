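id	name	formula
PFAS01	Pentaerythritol tetrakis(heptafluorobutyrate) (PFAS, DTXSID70325550)	C21H8F28O8
TRIT01	Dammarenediol II	C30H52O2
DAG01	1,2-Diacylglycerol (34:3)	C37H66O5
VITD01	Vitamin D2 (ergocalciferol)	C28H44O
CHOL01	Cholest-5-ene	C27H46
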