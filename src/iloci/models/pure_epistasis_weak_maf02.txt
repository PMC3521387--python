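# Weak variant of the concordant-homozygote epistasis model: same structure
# as pure_epistasis_strong_maf02 but with a much smaller penetrance contrast.
# Used for monotonicity checks (detection accuracy should not exceed the
# strong model's).  Synthetic reconstruction, not a published table.
type: model
L: 2
mafs: 0.2 0.2
label: pure-epistasis-weak
h2: weak
table:
0.05 0.02 0.02
0.02 0.02 0.02
0.02 0.02 0.05
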