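# id<TAB>smiles -- hydrogen-suppressed dications; chloride counterions omitted
# test-compound structures are transcriptions from the study's structure chart:
# descriptor values derived from them are not validated against any printed table
C12C6C12	CCCCCCCCCCCC[N+](C)(C)CCCCCC[N+](C)(C)CCCCCCCCCCCC
12-Py(2)-4-(2)Py-12	CCCCCCCCCCCC[n+]1ccccc1CCCCc1cccc[n+]1CCCCCCCCCCCC
p-[C14H29N+(CH3)2CH2CH(OH)CH2O]2C6H4	CCCCCCCCCCCCCC[N+](C)(C)CC(O)COc1ccc(cc1)OCC(O)C[N+](C)(C)CCCCCCCCCCCCCC
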