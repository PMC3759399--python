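{
 "said": "435008",
 "expression": {
  "op": "union",
  "args": [
   {
    "assay": "504701",
    "set": "active"
   },
   {
    "assay": "504699",
    "set": "active"
   }
  ]
 },
 "inactive_source": [
  "485270",
  "463079",
  "434989"
 ]
}
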