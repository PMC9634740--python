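{
  "comment": "Median screening thresholds reported for the original 117-node STRING export. The export itself is not redistributable, so these sextuples are reference values only; they cannot be re-derived here and are not asserted by tests. The round-2 betweenness value is inconsistent with the published hub-table betweenness column (all < 3.2) and is recorded as printed.",
  "round1": {
    "betweenness": 31.368076265,
    "closeness": 0.117252968,
    "degree": 6,
    "eigenvector": 0.0489839665,
    "lac": 2.45,
    "network": 3.3304473305
  },
  "round2": {
    "betweenness": 8.080020796,
    "closeness": 0.576923077,
    "degree": 9,
    "eigenvector": 0.145350322,
    "lac": 4.5,
    "network": 5.6
  }
}
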