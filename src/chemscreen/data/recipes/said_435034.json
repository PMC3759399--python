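{
 "said": "435034",
 "expression": {
  "op": "subtract",
  "args": [
   {
    "assay": "677",
    "set": "active"
   },
   {
    "assay": "860",
    "set": "active"
   }
  ]
 },
 "inactive_source": [
  "628"
 ]
}
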