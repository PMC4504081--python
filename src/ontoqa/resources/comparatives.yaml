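# Surface comparative phrases and the canonical pattern each rewrites to.
# The extractor first rewrites surface phrases to the canonical patterns,
# then converts canonical patterns plus a numeric literal into an
# (operand, operator, value) relation.
rewrite:
  "lower than": "less than"
  "smaller than": "less than"
  "fewer than": "less than"
  "below": "less than"
  "under": "less than"
  "higher than": "greater than"
  "larger than": "greater than"
  "more than": "greater than"
  "above": "greater than"
  "over": "greater than"
  "exceeding": "greater than"
  "no more than": "at most"
  "no less than": "at least"
  "equal to": "equals"
canonical:
  "greater than": ">"
  "less than": "<"
  "at least": ">="
  "at most": "<="
  "equals": "="
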