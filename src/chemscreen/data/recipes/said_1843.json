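{
 "said": "1843",
 "expression": {
  "op": "subtract",
  "args": [
   {
    "op": "intersect",
    "args": [
     {
      "assay": "2032",
      "set": "active"
     },
     {
      "assay": "463252",
      "set": "active"
     }
    ]
   },
   {
    "op": "union",
    "args": [
     {
      "assay": "2105",
      "set": "active"
     },
     {
      "assay": "2345",
      "set": "active"
     },
     {
      "assay": "2236",
      "set": "active"
     },
     {
      "assay": "2329",
      "set": "active"
     }
    ]
   }
  ]
 },
 "inactive_source": [
  "1672"
 ]
}
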