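# Two-site sequential distributive phosphorylation of substrate S by
# kinase E, with distinct phosphatases F1, F2 per site; Michaelis-Menten
# mechanism, mass-action kinetics.
r1: E + S0 -> ES0
r2: ES0 -> E + S0
r3: ES0 -> E + S1
r4: F1 + S1 -> F1S1
r5: F1S1 -> F1 + S1
r6: F1S1 -> F1 + S0
r7: E + S1 -> ES1
r8: ES1 -> E + S1
r9: ES1 -> E + S2
r10: F2 + S2 -> F2S2
r11: F2S2 -> F2 + S2
r12: F2S2 -> F2 + S1
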