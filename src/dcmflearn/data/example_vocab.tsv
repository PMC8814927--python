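CONCEPT	TYPE
C0000001	medication
C0000002	disease
C0000003	disease
C0000004	procedure
C0000005	medication
C0000006	disease
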