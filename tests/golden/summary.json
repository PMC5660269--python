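{
  "cluster_p_values": [
    1.6314e-09,
    3.51043e-06,
    0.0173892,
    0.0218628,
    0.3
  ],
  "cluster_sizes": [
    23,
    13,
    11,
    10,
    3
  ],
  "key_genes": [
    "G000008",
    "G000062"
  ],
  "n_bottlenecks": {
    "common": 2,
    "genes_a": 3,
    "genes_b": 2
  },
  "n_clusters": 5,
  "n_common_genes": 41,
  "n_enriched_terms": 2,
  "n_hub_bottlenecks_common": 0,
  "n_hubs": {
    "common": 0,
    "genes_a": 2,
    "genes_b": 2
  },
  "n_key_genes": 2,
  "n_shared_bottlenecks": 2,
  "n_shared_hubs": 2,
  "n_term_groups": 2,
  "networks": {
    "common": {
      "edges": 92,
      "nodes": 35
    },
    "genes_a": {
      "edges": 101,
      "nodes": 41
    },
    "genes_b": {
      "edges": 101,
      "nodes": 40
    }
  },
  "size_a": 49,
  "size_b": 49
}
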