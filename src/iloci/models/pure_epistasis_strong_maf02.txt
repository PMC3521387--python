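# Synthetic reconstruction of a strong two-locus epistasis model family:
# disease risk is concentrated on concordant homozygote combinations
# (w,w) and (v,v), with a small baseline elsewhere.  Because the pair
# statistic is driven by homozygote-homozygote joint cells, this pattern
# produces a large case/control dependence contrast at the disease pair.
# Not a verbatim published penetrance table.
type: model
L: 2
mafs: 0.2 0.2
label: pure-epistasis-strong
h2: strong
table:
0.40 0.02 0.02
0.02 0.02 0.02
0.02 0.02 0.40
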