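# Synthetic reconstruction of a four-locus interaction-network model: a
# chain of three pairwise concordant-homozygote interactions combined under
# the heterogeneity rule (each edge is an independent route to disease,
# joint penetrance 1 - prod(1 - p_edge)).  Not a verbatim published table.
type: network
combine: heterogeneity
label: het-network-4locus
h2: strong
node: L1 0.25
node: L2 0.25
node: L3 0.25
node: L4 0.25
edge: L1 L2
0.25 0.01 0.01
0.01 0.01 0.01
0.01 0.01 0.25
edge: L2 L3
0.25 0.01 0.01
0.01 0.01 0.01
0.01 0.01 0.25
edge: L3 L4
0.25 0.01 0.01
0.01 0.01 0.01
0.01 0.01 0.25
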