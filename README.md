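# phantomdose

Effective-dose analysis for point dosimetry in anthropomorphic phantoms.

When an extremity such as the elbow is imaged with radiography, multi-slice
CT (MSCT) or cone-beam CT (CBCT), the stochastic health risk is compared via
the ICRP 103 effective dose. In a layered RANDO-type phantom the absorbed
dose is only known at the points where MOSFET dosimeters sit, so each organ's
equivalent dose is built from the irradiated mass fraction of its
sub-structures:

```
H_T = w_R * Σ_i f_i · D_Ti          E = Σ_T w_T · H_T
```

where `D_Ti` is the mean absorbed dose (mGy) of the dosimeters assigned to
sub-structure `i`, `f_i` its irradiated mass fraction (mass inside the
exposed volume over whole-body tissue mass), `w_R = 1 Sv/Gy` for photons and
`w_T` the ICRP 103 tissue weighting factors. Remainder organs (muscle,
lymphatic nodes) share the collective remainder weight over the 13 ICRP 103
remainder organs. `phantomdose` implements this pipeline end to end:

* **dose engine** — equivalent doses, weighted contributions, effective
  dose, mAs-normalised dose, dose ratios, ratio correlation and group
  differences expressed in days of background radiation;
* **fraction estimation** — irradiated mass fractions from layered phantom
  geometry and reference anatomy (one-third active marrow rule,
  bone surface-to-volume ratios, Du Bois skin area, 28 000 g muscle mass,
  5 % cubital-node share);
* **uncertainty** — type A replicate scatter and type B components
  propagated by weighted sums of variances to a combined 1 SD / expanded
  2 SD budget;
* **synthetic data** — a lognormal replicate generator matching the
  measured noise structure (per-replicate CV 15–48 %), for testing every
  stage without the physical phantom;
* **io/reporting** — CSV/YAML/JSON readers and writers, a JSON report at
  full precision, rounded comparison tables and a CLI.

A measured reference study is bundled: per-dosimeter absorbed doses of
seven elbow protocols (conventional radiography AP+LAT, one MSCT protocol,
four NewTom 5G CBCT settings, one Planmed Verity CBCT setting), the ICRP 103
elbow tissue map and the protocol metadata.

## Worked example

```python
from phantomdose import reference_dataset, effective_dose, collapse_replicates
from phantomdose.io import split_by_protocol

readings, tissue_map, protocols = reference_dataset()
doses = collapse_replicates(split_by_protocol(readings)["siemens_msct"])
result = effective_dose(doses, tissue_map, protocols["siemens_msct"])
for organ, usv in result.weighted_contribution_by_organ.items():
    print(f"{organ:16s} {usv:6.1f} uSv  ({result.contribution_percent[organ]:4.1f} %)")
print(f"effective dose   {result.effective_dose_usv:6.1f} uSv")
print(f"normalized       {result.normalized_effective_dose:6.2f} uSv/mAs")
```

prints

```
bone marrow        18.2 uSv  (49.6 %)
bone surface        3.0 uSv  ( 8.1 %)
skin                5.3 uSv  (14.6 %)
lymphatic nodes     8.5 uSv  (23.3 %)
muscle              1.6 uSv  ( 4.4 %)
effective dose     36.6 uSv
normalized         0.32 uSv/mAs
```

— the MSCT elbow scan deposits an effective dose of ~37 µSv, half of it in
bone marrow, at 0.32 µSv per mAs; the CBCT protocols in the same dataset
land between 1.9 and 6.1 µSv. The same numbers are available from the shell:

```
phantomdose compute \
    --readings src/phantomdose/data/elbow_readings.csv \
    --tissue-map src/phantomdose/data/icrp103_elbow.yaml \
    --protocols src/phantomdose/data/elbow_protocols.json \
    --out report.json --tables-dir tables/
```

`phantomdose simulate` generates synthetic replicate readings and
`phantomdose fractions` re-derives a tissue map from phantom geometry and
reference anatomy.

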