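# ICRP 103 elbow tissue map: tissue weighting factors, irradiated mass
# fractions and the dosimeters assigned to each sub-structure.
w_R: 1.0
remainder_organ_count: 13
organs:
- organ: bone marrow
  w_T: 0.12
  is_remainder: false
  substructures:
  - name: Ulna
    f_i: 0.0019
    dosimeters:
    - 7
    - 8
    - 10
    - 11
  - name: Radius
    f_i: 0.0021
    dosimeters:
    - 6
    - 8
    - 10
    - 11
  - name: Humerus
    f_i: 0.006
    dosimeters:
    - 1
    - 2
    - 5
    - 6
- organ: bone surface
  w_T: 0.01
  is_remainder: false
  substructures:
  - name: Ulna
    f_i: 0.004
    dosimeters:
    - 6
    - 9
  - name: Radius
    f_i: 0.0039
    dosimeters:
    - 6
    - 9
  - name: Humerus
    f_i: 0.0093
    dosimeters:
    - 1
    - 2
    - 5
    - 6
- organ: skin
  w_T: 0.01
  is_remainder: false
  substructures:
  - name: Flexor carpi ulnaris
    f_i: 0.0083
    dosimeters:
    - 9
  - name: Extensor carpi radialis longus
    f_i: 0.008
    dosimeters:
    - 8
  - name: Bicep
    f_i: 0.0081
    dosimeters:
    - 4
  - name: Tricep
    f_i: 0.0042
    dosimeters:
    - 3
- organ: lymphatic nodes
  w_T: 0.12
  is_remainder: true
  substructures:
  - name: Cubital nodes
    f_i: 0.05
    dosimeters:
    - 6
- organ: muscle
  w_T: 0.12
  is_remainder: true
  substructures:
  - name: Flexor carpi ulnaris
    f_i: 0.0004
    dosimeters:
    - 9
  - name: Extensor carpi radialis longus
    f_i: 0.0005
    dosimeters:
    - 6
  - name: Brachioradialis
    f_i: 0.0018
    dosimeters:
    - 6
  - name: Bicep
    f_i: 0.0022
    dosimeters:
    - 4
  - name: Tricep
    f_i: 0.004
    dosimeters:
    - 3
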