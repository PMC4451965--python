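# Ring1B/Bmi1 histone-H2A ubiquitination model (degradation omitted).
# B = Bmi1, R = Ring1B, Z = Bmi1/Ring1B complex, H = histone H2A;
# the "ubd" forms are ubiquitinated and targeted for degradation,
# "ub"/"uba" are other (self-)ubiquitinated forms.
r1: B -> Bubd
r2: Bubd -> B
r3: R -> Rubd
r4: Rubd -> R
r5: B + R -> Z
r6: Z -> B + R
r7: Z -> Zub
r8: Zub -> Z
r9: Zub -> B + Ruba
r10: B + Ruba -> Zub
r11: R -> Rub
r12: Rub -> R
r13: Ruba -> R
r14: H -> Hub
r15: Hub -> H
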