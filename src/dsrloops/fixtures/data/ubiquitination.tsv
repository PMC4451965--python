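# Influence signs read off the published rate functions, one row per
# species; every rate is strictly increasing in each variable it uses.
#   v1  = k1*B                      -> B+ in r1
#   v2  = k2*Bubd                   -> Bubd+ in r2
#   v3  = k3*R                      -> R+ in r3
#   v4  = k4*Rubd                   -> Rubd+ in r4
#   v5  = k5*B*R                    -> B+, R+ in r5
#   v6  = k6*Z                      -> Z+ in r6
#   v7  = Z*(k7*Z + k8*Zub)         -> Z+, Zub+ in r7 (product feeds back)
#   v8  = k9*Zub/(k10 + Zub)        -> Zub+ in r8
#   v9  = k11*Zub                   -> Zub+ in r9
#   v10 = k12*B*Ruba                -> B+, Ruba+ in r10
#   v11 = k13*R^2 + k14*R*Rub       -> R+, Rub+ in r11 (product feeds back)
#   v12 = k14*Rub                   -> Rub+ in r12
#   v13 = k15*Ruba                  -> Ruba+ in r13
#   v14 = H*(k16*Rub + k17*Zub + k18*Ruba) -> H+, Rub+, Zub+, Ruba+ in r14
#   v15 = k19*Hub                   -> Hub+ in r15
species	r1	r2	r3	r4	r5	r6	r7	r8	r9	r10	r11	r12	r13	r14	r15
B	+	0	0	0	+	0	0	0	0	+	0	0	0	0	0
Bubd	0	+	0	0	0	0	0	0	0	0	0	0	0	0	0
R	0	0	+	0	+	0	0	0	0	0	+	0	0	0	0
Rubd	0	0	0	+	0	0	0	0	0	0	0	0	0	0	0
Z	0	0	0	0	0	+	+	0	0	0	0	0	0	0	0
Zub	0	0	0	0	0	0	+	+	+	0	0	0	0	+	0
Ruba	0	0	0	0	0	0	0	0	0	+	0	0	+	+	0
Rub	0	0	0	0	0	0	0	0	0	0	+	+	0	+	0
H	0	0	0	0	0	0	0	0	0	0	0	0	0	+	0
Hub	0	0	0	0	0	0	0	0	0	0	0	0	0	0	+
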