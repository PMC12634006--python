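subject_id,test,retest
S0,1.3453,1.5138
S1,1.3314,1.3903
S2,1.0961,1.0893
S3,1.164,1.2235
S4,1.1931,1.3374
S5,1.2877,1.1894
S6,1.9157,1.8051
S7,1.0369,1.1479
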