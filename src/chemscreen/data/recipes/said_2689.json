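{
 "said": "2689",
 "expression": {
  "op": "subtract",
  "args": [
   {
    "assay": "2821",
    "set": "active"
   },
   {
    "assay": "504583",
    "set": "active"
   }
  ]
 },
 "inactive_source": [
  "2661"
 ]
}
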