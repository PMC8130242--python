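# SYNTHETIC calibration geometry of a layered adult elbow phantom.
# The real phantom's slice-by-slice measurements are not published;
# this reconstruction is calibrated so that the five organ-level
# irradiated-fraction totals reproduce the study's values
# (RBM 1.00%, bone surface 1.72%, skin 2.86%, muscle 0.89%, lymph 5%).
layer_thickness_cm: 2.5
exposed_layers:
- 11
- 12
- 13
- 14
- 15
- 16
- 17
layers:
- index: 11
  perimeter_cm: 27.0
  bones:
    ulna: 0.7
    radius: 0.6
  muscles:
    flexor carpi ulnaris: 16.0
    extensor carpi radialis longus: 14.0
- index: 12
  perimeter_cm: 27.8
  bones:
    ulna: 0.8
    radius: 0.7
  muscles:
    flexor carpi ulnaris: 14.0
    extensor carpi radialis longus: 14.0
    brachioradialis: 18.0
- index: 13
  perimeter_cm: 28.6
  bones:
    ulna: 1.0
    radius: 0.8
  muscles:
    brachioradialis: 22.0
- index: 14
  perimeter_cm: 30.2
  bones:
    ulna: 1.3
    humerus: 1.2
  muscles:
    bicep: 24.0
    tricep: 26.0
- index: 15
  perimeter_cm: 32.4
  bones:
    humerus: 1.3737864078
  muscles:
    bicep: 20.0
    tricep: 30.0
- index: 16
  perimeter_cm: 34.0
  bones:
    humerus: 1.3
  muscles:
    bicep: 16.0
    tricep: 20.0
- index: 17
  perimeter_cm: 35.7901323187
  bones:
    humerus: 1.1
  muscles:
    tricep: 15.2
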