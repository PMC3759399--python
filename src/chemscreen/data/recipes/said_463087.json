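{
 "said": "463087",
 "expression": {
  "op": "subtract",
  "args": [
   {
    "assay": "489005",
    "set": "active"
   },
   {
    "op": "union",
    "args": [
     {
      "assay": "493021",
      "set": "inactive"
     },
     {
      "assay": "493022",
      "set": "inactive"
     },
     {
      "assay": "493023",
      "set": "inactive"
     },
     {
      "assay": "493041",
      "set": "inactive"
     }
    ]
   }
  ]
 },
 "inactive_source": [
  "449739"
 ]
}
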