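# SYNTHETIC reference anatomy: whole-body constants (adult reference
# values: marrow 4% of body weight, one-third active; 28 000 g muscle;
# Du Bois surface area at 70 kg / 180 cm; 5% cubital-node share) plus
# per-bone surface-to-volume ratios, fresh-weight shares and irradiated
# length fractions, which are free parameters calibrated jointly with
# the companion geometry file to the study's bone-surface total (1.72%).
rbm_density_g_cm3: 1.03
active_marrow_share: 0.3333333333333333
total_body_bm_share_of_weight: 0.04
bone_surface_to_volume_cm2_cm3:
  ulna: 15.0
  radius: 15.0
  humerus: 12.0
  whole body: 10.0
fresh_bone_weight_percent:
  ulna: 0.65
  radius: 0.5
  humerus: 1.07
bone_length_irradiated_fraction:
  ulna: 0.6
  radius: 0.55
  humerus: 0.56269470405
skeleton_fresh_mass_g: 10500.0
bone_density_g_cm3: 1.3
total_body_muscle_mass_g: 28000.0
body_mass_kg: 70.0
body_height_cm: 180.0
lymph_fraction: 0.05
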