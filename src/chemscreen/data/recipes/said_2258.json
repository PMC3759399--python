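{
 "said": "2258",
 "expression": {
  "op": "subtract",
  "args": [
   {
    "assay": "2287",
    "set": "active"
   },
   {
    "op": "union",
    "args": [
     {
      "assay": "2282",
      "set": "active"
     },
     {
      "assay": "2283",
      "set": "active"
     },
     {
      "assay": "2558",
      "set": "active"
     }
    ]
   }
  ]
 },
 "inactive_source": [
  "2239"
 ]
}
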