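# Unregulated single gene: c == 1, stationary protein law ~ Gamma(km/gx, kx/gm).
n_genes: 1
topology:
- [0]
genes:
- {km: 10.0, kx: 5.0, gm: 5.0, gx: 1.0, eps: 0.0}
edges: []
names: [reporter]
input_function: product_of_hills
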