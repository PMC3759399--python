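{
 "said": "488997",
 "expression": {
  "op": "subtract",
  "args": [
   {
    "op": "intersect",
    "args": [
     {
      "assay": "493221",
      "set": "active"
     },
     {
      "assay": "504840",
      "set": "active"
     },
     {
      "assay": "588401",
      "set": "active"
     }
    ]
   },
   {
    "assay": "493222",
    "set": "active"
   },
   {
    "assay": "602208",
    "set": "inactive"
   }
  ]
 },
 "inactive_source": [
  "488975"
 ]
}
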