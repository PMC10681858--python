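# Three-gene repression ring with strong cooperativity: noisy oscillations,
# visible as a positive-lag peak of the protein autocorrelation.
n_genes: 3
topology:
- [0, 0, -1]
- [-1, 0, 0]
- [0, -1, 0]
genes:
- {km: 25.0, kx: 20.0, gm: 5.0, gx: 1.0, eps: 0.02}
- {km: 25.0, kx: 20.0, gm: 5.0, gx: 1.0, eps: 0.02}
- {km: 25.0, kx: 20.0, gm: 5.0, gx: 1.0, eps: 0.02}
edges:
- {i: 0, j: 2, K: 40.0, n: 4.0}
- {i: 1, j: 0, K: 40.0, n: 4.0}
- {i: 2, j: 1, K: 40.0, n: 4.0}
names: [lacI, tetR, cI]
input_function: product_of_hills
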