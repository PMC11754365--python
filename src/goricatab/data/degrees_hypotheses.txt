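# Competing hypotheses on the four male-given-degree conditional proportions
H1: eta1 > {eta2, eta3, eta4}
H2: eta1 = eta2, eta3 > eta4
H3: eta1 > eta2 > eta3 > eta4
Hu: eta1, eta2, eta3, eta4
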