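SUBJECT_CUI	PREDICATE	OBJECT_CUI
C0000001	TREATS	C0000002
C0000002	CAUSES	C0000003
C0000003	PART_OF	C0000004
C0000001	LOCATION_OF	C0000005
C0000004	NEG_TREATS	C0000005
C0000009	TREATS	C0000002
C0000005	AFFECTS	C0000099
C0000005	TREATS	C0000006
C0000006	COEXISTS_WITH	C0000001
C0000002	PREVENTS	C0000006
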