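temperature_K,kc_per_M,label
293.15,42,AA/bCD
303.15,60,AA/bCD
313.15,73,AA/bCD
323.15,80,AA/bCD
293.15,209,AA/DMbCD
303.15,219,AA/DMbCD
313.15,232,AA/DMbCD
323.15,237,AA/DMbCD
293.15,88,AA/HPbCD
303.15,112,AA/HPbCD
313.15,135,AA/HPbCD
323.15,148,AA/HPbCD
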