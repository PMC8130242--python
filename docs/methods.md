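# Methods

## Dose model

The package computes ICRP 103 effective doses for partial-body exposures
measured with point dosimeters in a layered anthropomorphic phantom. The
equivalent dose of tissue T is `H_T = w_R Σ_i f_i · D_Ti`, summed over the
tissue's sub-structures in the exposed layers; the effective dose is
`E = Σ_T w_T · H_T`. All internal arithmetic is double precision; readings
enter in mGy and equivalent/effective doses are reported in µSv (factor
1000 at `w_R = 1 Sv/Gy`). Rounding happens only in rendered tables
(default one decimal, two for the mAs-normalised dose), never in the JSON
report.

Choices that the standard formulation leaves open, and how this package
resolves them:

* **Multi-dosimeter sub-structures.** When a sub-structure lists several
  dosimeters (e.g. four dosimeters along the ulna), its absorbed dose is
  their arithmetic mean, then multiplied by `f_i`. This matches the "average
  absorbed dose in layer i" reading of the model and reproduces the bundled
  study's published per-organ contributions within rounding.
* **Remainder organs.** Remainder organs do not carry `w_T` individually;
  each receives `w_remainder / N` with `N = 13` remainder organs (ICRP 103
  convention, configurable via `TissueMap.remainder_organ_count`). With the
  bundled data this reproduces the published lymphatic-node (8.5 µSv) and
  muscle (1.6 µSv) MSCT contributions to within 0.05 µSv.
* **Sub-exposures.** A protocol may consist of several exposures whose
  doses add (AP plus LAT radiographic projections): replicates are averaged
  within an exposure, then exposures are summed per dosimeter.
* **Replicates.** Replicates collapse to per-dosimeter means before any
  dose arithmetic; their scatter is consumed only by the uncertainty module.
* **Degenerate inputs.** Zero effective dose makes percent contributions,
  shares and ratios undefined: they are reported as absent (`None`/JSON
  null) with a logged warning, never NaN. A zero-dose baseline protocol
  raises rather than emitting infinite ratios.

The Pearson product-moment coefficient is used for the correlation between
effective-dose and mean-absorbed-dose ratio vectors (the choice of
correlation statistic is free; Pearson is the field default for such
linear-agreement checks and is invariant to the positive baseline choice).
Dose differences between modality groups are optionally expressed in days
of natural background radiation at 3.1 mSv/yr (configurable).

## Irradiated fractions

`f_i` is the tissue mass inside the exposed volume over the whole-body
tissue mass. The estimators operate on a layered geometry description
(default layer thickness 2.5 cm) and a reference-anatomy table:

* **Red bone marrow** — marrow volume = Σ bone cross-sections × layer
  thickness over the exposed layers; the active (red) share is one third
  (adult reference); whole-body marrow is 4 % of body weight. With the
  active share applied to both numerator and denominator it cancels in the
  fraction.
* **Bone surface** — per exposed bone: whole-bone volume from its
  fresh-weight share of the skeleton, surface via the per-bone
  surface-to-volume ratio, exposed surface via the irradiated length
  fraction; denominator: skeleton-wide surface-to-volume ratio times
  skeleton volume. Skeleton mass and bone density cancel in the ratio and
  act only as intermediate scales.
* **Skin** — exposed area = Σ layer perimeters × thickness; whole-body
  area from the Du Bois formula `0.007184 · m^0.425 · h^0.725` (m², from kg
  and cm; constants configurable).
* **Muscle** — Σ per-layer muscle masses over the 28 000 g whole-body
  reference mass.
* **Lymphatic nodes** — a configured constant (default 5 %, the
  cubital-node share matching the popliteal-fossa share observed in
  whole-body lymphoscintigraphy).

The bundled geometry and anatomy files are *synthetic reconstructions*
(labelled so in their filenames): the real phantom's slice measurements are
not published, so a calibration geometry was constructed once to reproduce
the study's five organ-level totals — red bone marrow 1.00 %, bone surface
1.72 %, skin 2.86 %, muscle 0.89 %, lymph 5.00 % (the sums of the published
per-sub-structure fractions). One bone cross-section, one perimeter, one
muscle mass and the humerus irradiated-length fraction are the closing
parameters of that calibration; all other values are round, anatomically
plausible numbers. The split of an organ total into per-sub-structure
fractions is not derivable from layer geometry, so `build_tissue_map`
distributes estimated totals proportionally to a template tissue map's
split; with the bundled inputs this regenerates the bundled ICRP 103 elbow
map to machine precision. Consequences for testing: estimator acceptance on
these files demonstrates internal consistency of the estimators with the
published totals, not agreement with independently measured phantom
geometry.

Only the volume-based marrow assessment is implemented; the alternative
literature-distribution assessment mentioned alongside it is not specified
enough to reproduce and is out of scope.

## Uncertainty model

All components are relative 1 SD percentages, assumed independent and
combined in quadrature. Defaults (configurable via the budget YAML):
dosimeter position 10 %, phantom position 10 % (per dosimeter), x-ray
source variation 5 %, cable irradiation 1 % (global), irradiated fraction
25 % (per tissue sub-structure).

* **Type A** is the relative standard deviation *of the mean* of the
  replicate set, `s / (mean √n)` — the replicates are averaged before the
  dose enters the pipeline — with a switch (`of_mean=False`) for the
  per-measurement convention. The observed per-dosimeter replicate CVs of
  the reference study span 15–48 %; at n = 10 the corresponding type A
  values span 4.7–15.2 %.
* **Per tissue**: per-dosimeter uncertainties (type A ⊕ per-dosimeter
  type B) combine in a quadrature weighted by each dosimeter's share of
  `H_T`; the fraction component enters once per sub-structure, weighted by
  the sub-structure's share of `H_T`. Positioning errors of distinct
  dosimeters are treated as independent (hence the damping), while source
  output and cable effects are coherent across a scan and therefore enter
  once at the effective-dose level.
* **Effective dose**: relative variance = Σ_T (share of T)² · u_T² plus
  the global components; expanded uncertainty uses coverage factor k = 2,
  exactly (`expanded = 2 × combined` before any report rounding).

Under this split, drawing per-dosimeter replicate CVs uniformly from the
observed 15–48 % range yields combined 1 SD values of 12–15 % (at integer
printing precision) for all seven bundled protocols — consistent with the
study's published per-protocol budget. The exact per-dosimeter type A
values of the study are not published, so this is a consistency band, not a
point reproduction. No correlated-uncertainty (full GUM) treatment is
attempted.

## Synthetic data

The generator draws `replicate_count` (default 10) readings per
(protocol, dosimeter) with mean equal to the configured true dose and
per-replicate coefficient of variation `noise_cv` (default: the 11
dosimeters span 15–48 %). Noise is lognormal by default: doses are strictly
positive and at 48 % CV a normal model would cross zero. The lognormal is
parameterised mean-exactly (`σ² = ln(1+cv²)`, `µ = ln(true) − σ²/2`), so
the linear dose pipeline is exactly unbiased on synthetic data — the
end-to-end recovery test exploits this. A truncated-normal option exists
for sensitivity checks; its redraw-based truncation biases the mean
slightly upward at large CV, which is why it is not the default.

Each (protocol, dosimeter) pair gets its own RNG stream keyed by
(seed, CRC32 of the protocol id, dosimeter id), so datasets are
reproducible byte-for-byte and adding a protocol never perturbs existing
draws.

What the generator does *not* emulate: dose-level-dependent MOSFET
sensitivity drift, angular response, inter-dosimeter calibration offsets,
or any beam physics — noise is purely statistical around a configured
truth. Tests passing on synthetic data therefore validate the estimators
and their propagation arithmetic, not the physical measurement chain.

A note on estimator bias: the replicate-CV estimator `s/mean` is biased
low at small n (≈ 4–8 % relative at n = 10 over the 15–48 % CV range), so
recovery tests compare the generator-plus-estimator path against an
independent simulation of the same statistic rather than asserting exact
unbiasedness; the effective-dose estimator itself is exactly unbiased and
is tested as such.

## Problem sizes

Everything runs at desk scale: the reference analysis is 7 protocols × 11
dosimeters; property tests use tissue maps of ≤ 5 organs and ≤ 11
dosimeters; Monte-Carlo checks use 500–1000 synthetic replicate sets (10
replicates each), chosen to make 3-standard-error bands a few tenths of a
percentage point wide. The full suite completes in a few seconds.

## Known limitations

* The published absorbed doses are rounded to one decimal and the
  fractions to two significant digits; recomputed effective doses
  therefore sit up to ~9 % below the published (unrounded-input) values.
  The recomputed MSCT bone-marrow contribution is 18.2 µSv against the
  published 19.0 µSv for the same reason.
* Adult ICRP 103 weighting factors only; no pediatric or age-dependent
  marrow distribution beyond the configurable active-marrow share.
* The bundled geometry/anatomy fixtures are calibrated reconstructions
  (see above), not measurements.
* No photon transport, beam modelling or image-quality analysis: the
  pipeline starts from measured or simulated point doses.
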