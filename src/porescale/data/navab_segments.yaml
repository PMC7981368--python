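# Approximate transmembrane-segment residue ranges for the homotetrameric
# bacterial sodium channel NavAb (e.g. PDB entry 3RVY).  Ranges apply to
# every chain (chain: "*").  Boundaries between helices are approximate;
# adjust against the structure's annotation before quantitative use.
segments:
  - {chain: "*", res_start: 8,   res_end: 31,  segment: S1}
  - {chain: "*", res_start: 37,  res_end: 61,  segment: S2}
  - {chain: "*", res_start: 68,  res_end: 88,  segment: S3}
  - {chain: "*", res_start: 90,  res_end: 111, segment: S4}
  - {chain: "*", res_start: 112, res_end: 120, segment: S4S5_linker}
  - {chain: "*", res_start: 121, res_end: 149, segment: S5}
  - {chain: "*", res_start: 150, res_end: 174, segment: P_helix}
  - {chain: "*", res_start: 175, res_end: 179, segment: SF}
  - {chain: "*", res_start: 180, res_end: 189, segment: P2_helix}
  - {chain: "*", res_start: 190, res_end: 221, segment: S6}
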