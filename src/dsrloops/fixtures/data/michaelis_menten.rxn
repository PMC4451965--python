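# Bare Michaelis-Menten mechanism; on its own it cannot be
# multistationary.
r1: S0 + E -> ES0
r2: ES0 -> S0 + E
r3: ES0 -> S1 + E
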