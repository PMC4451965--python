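# Influence signs for the mitosis toy model with a phosphorylation rate
# that depends on Xnuc only (no self-activation of r3).
species	r1	r2	r3	r4
Xcyt	+	0	0	0
Xnuc	0	+	+	0
Xnucp	0	0	0	+
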