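{
 "ac_pt_degrees_direct_indirect": {
  "AC11": 5,
  "AC12": 1,
  "AC13": 1,
  "AC14": 1,
  "AC15": 1,
  "AC16": 2,
  "AC2": 5,
  "AC3": 8,
  "AC31": 1,
  "AC32": 1,
  "AC37": 1,
  "AC39": 1,
  "AC4": 1,
  "AC40": 1,
  "AC41": 1,
  "AC42": 2,
  "AC43": 1,
  "AC44": 1,
  "AC49": 1,
  "AC5": 6,
  "AC54": 3,
  "AC58": 2,
  "AC6": 4,
  "AC60": 1,
  "AC7": 2,
  "AC9": 2
 },
 "edge_counts_by_kind": {
  "contains": 14,
  "implicated_in": 12,
  "participates_in": 32,
  "targets_direct": 48,
  "targets_indirect": 8
 },
 "node_counts": {
  "compound": 57,
  "disease": 13,
  "pathway": 44,
  "plant": 29,
  "target": 65
 },
 "structure_count": 25
}
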