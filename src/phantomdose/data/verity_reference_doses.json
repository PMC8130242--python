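{
 "description": "Reference effective doses (uSv) of the Planmed Verity CBCT at standard-dose kVp/mA settings; shipped for comparison only, never computed by this package.",
 "effective_dose_usv": {
  "80 kVp": {
   "3.8 mA": 1.15,
   "7.5 mA": 2.27,
   "12 mA": 3.63
  },
  "84 kVp": {
   "3.8 mA": 1.34,
   "7.5 mA": 2.65,
   "12 mA": 4.24
  },
  "88 kVp": {
   "3.8 mA": 1.63,
   "7.5 mA": 3.21,
   "12 mA": 5.14
  },
  "90 kVp": {
   "3.8 mA": 1.74,
   "7.5 mA": 3.44,
   "12 mA": 5.5
  },
  "92 kVp": {
   "3.8 mA": 1.96,
   "7.5 mA": 3.88,
   "12 mA": 6.2
  },
  "96 kVp": {
   "3.8 mA": 2.3,
   "7.5 mA": 4.54,
   "12 mA": 7.26
  }
 }
}
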