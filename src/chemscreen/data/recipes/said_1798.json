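{
 "said": "1798",
 "expression": {
  "op": "subtract",
  "args": [
   {
    "assay": "1488",
    "set": "active"
   },
   {
    "assay": "1741",
    "set": "active"
   }
  ]
 },
 "inactive_source": [
  "626"
 ]
}
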