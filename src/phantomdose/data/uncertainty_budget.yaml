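# Default type B uncertainty components (relative 1SD, percent).
components:
- name: dosimeter position
  relative_1sd_percent: 10.0
  applies_to: per_dosimeter
- name: phantom position
  relative_1sd_percent: 10.0
  applies_to: per_dosimeter
- name: x-ray source variation
  relative_1sd_percent: 5.0
  applies_to: global
- name: cable irradiation
  relative_1sd_percent: 1.0
  applies_to: global
- name: fraction irradiated
  relative_1sd_percent: 25.0
  applies_to: per_tissue
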