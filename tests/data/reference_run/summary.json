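{
 "edges_by_K_plus_k": {
  "K0+1": 1,
  "K1+1": 1
 },
 "fraction_above_diagonal": 1.0,
 "n_clusters": 3,
 "n_edges": 2,
 "n_nodes": 5,
 "n_records": 28
}
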