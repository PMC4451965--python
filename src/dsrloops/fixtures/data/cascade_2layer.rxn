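# Two-layer phosphorylation cascade with explicit positive feedback:
# layer 1 (kinase E, phosphatase F1) produces S1, which is the kinase of
# layer 2 (phosphatase F2); the layer-2 product P1 converts into E (r13).
r1: E + S0 -> ES0
r2: ES0 -> E + S0
r3: ES0 -> E + S1
r4: F1 + S1 -> F1S1
r5: F1S1 -> F1 + S1
r6: F1S1 -> F1 + S0
r7: S1 + P0 -> S1P0
r8: S1P0 -> S1 + P0
r9: S1P0 -> S1 + P1
r10: F2 + P1 -> F2P1
r11: F2P1 -> F2 + P1
r12: F2P1 -> F2 + P0
r13: P1 -> E
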