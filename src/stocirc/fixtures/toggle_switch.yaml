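# Two mutually repressing genes (cooperativity 2): bimodal stationary law.
n_genes: 2
topology:
- [0, -1]
- [-1, 0]
genes:
- {km: 16.0, kx: 5.0, gm: 5.0, gx: 1.0, eps: 0.05}
- {km: 16.0, kx: 5.0, gm: 5.0, gx: 1.0, eps: 0.05}
edges:
- {i: 0, j: 1, K: 3.0, n: 2.0}
- {i: 1, j: 0, K: 3.0, n: 2.0}
names: [lacI, tetR]
input_function: product_of_hills
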