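# Synthetic reconstruction of a multiplicative two-locus model family with
# marginal effects at MAF 0.5: penetrance b*(1+theta)^(v1+v2) with b=0.05,
# theta=0.5, where v_l counts variant alleles at locus l.  Both loci show
# single-SNP association as well as interaction.  Not a verbatim published
# penetrance table.
type: model
L: 2
mafs: 0.5 0.5
label: marginal-multiplicative
h2: moderate
table:
0.05    0.075   0.1125
0.075   0.1125  0.16875
0.1125  0.16875 0.253125
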