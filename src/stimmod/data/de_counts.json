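{
 "BAFF": {
  "down": 39,
  "total": 129,
  "up": 69
 },
 "CD40L": {
  "down": 496,
  "total": 1194,
  "up": 689
 },
 "IL21": {
  "down": 439,
  "total": 902,
  "up": 463
 },
 "LPS": {
  "down": 169,
  "total": 283,
  "up": 114
 },
 "aIgM": {
  "down": 3557,
  "total": 6596,
  "up": 3039
 }
}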