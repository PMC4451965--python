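# Basic caspase-activation model of apoptosis; C8a/C3a are the active
# caspases, IAP the inhibitor, Y the C3a-IAP complex.  Mass-action.
r1: C8a + C3 -> C8a + C3a
r2: C8 + C3a -> C8a + C3a
r3: C3a + IAP -> Y
r4: Y -> 0
r5: C3a + IAP -> C3a
r6: C8 -> 0
r7: 0 -> C8
r8: C3 -> 0
r9: 0 -> C3
r10: IAP -> 0
r11: 0 -> IAP
r12: C8a -> 0
r13: C3a -> 0
r14: Y -> C3a + IAP
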