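{
 "said": "485290",
 "expression": {
  "assay": "489007",
  "set": "active"
 },
 "inactive_source": [
  "485290"
 ]
}
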