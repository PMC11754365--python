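# Interaction (H1, H2) vs no-interaction (H3, H4) hypotheses on 12 two-way
# marginal gaze probabilities:
# eta1..eta12 = (p11+, p1+1, p22+, p2+2, p33+, p3+3, p34+, p3+4,
#                p43+, p4+3, p44+, p4+4)
H1: eta1 > eta2, eta3 > eta4, eta5 > eta6, eta11 > eta12
H2: eta1 > eta2, eta3 > eta4, eta7 > eta8, eta9 > eta10
H3: eta1 = eta2, eta3 = eta4, eta5 = eta6, eta11 = eta12
H4: eta1 = eta2, eta3 = eta4, eta7 = eta8, eta9 = eta10
Hu: eta1, eta2, eta3, eta4, eta5, eta6, eta7, eta8, eta9, eta10, eta11, eta12
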