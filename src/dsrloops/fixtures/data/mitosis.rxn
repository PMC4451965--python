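# Toy model of the onset of mitosis: shuttling of the Cdk1-cyclin B1
# complex between cytoplasm (Xcyt) and nucleus (Xnuc), and its nuclear
# phosphorylation (Xnucp).
r1: Xcyt -> Xnuc
r2: Xnuc -> Xcyt
r3: Xnuc -> Xnucp
r4: Xnucp -> Xnuc
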