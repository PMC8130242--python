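"""Irradiated tissue mass fractions from phantom geometry and reference anatomy.

The irradiated fraction f_i of a tissue is the mass of that tissue inside
the exposed volume divided by the tissue's whole-body mass. For a layered
phantom the exposed masses come from simple geometry — bone cross-sections,
layer perimeters and per-layer muscle masses, each multiplied by the layer
thickness — while the whole-body denominators come from reference anatomy:

* red bone marrow: bone-marrow volume in the exposed layers times marrow
  density, of which the active (red) share is one third; the whole-body
  red-marrow mass follows from total marrow being 4 % of body weight.
* bone surface: per-bone surface-to-volume ratios applied to whole-bone
  volumes (fresh-weight shares of the skeleton), scaled by the irradiated
  length fraction of each bone, against the skeleton-wide surface.
* skin: layer perimeters times thickness, against the whole-body surface
  area from the Du Bois formula 0.007184 * mass^0.425 * height^0.725.
* muscle: per-layer muscle masses against the 28 000 g whole-body mass.
* lymphatic nodes: a configured constant share (5 % for the cubital nodes,
  matching the popliteal-fossa share seen in lymphoscintigraphy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import yaml

from .models import ConfigurationError, OrganEntry, Substructure, TissueMap

#: Du Bois & Du Bois body-surface-area constants (m^2 from kg and cm).
DU_BOIS_COEFF = 0.007184
DU_BOIS_MASS_EXP = 0.425
DU_BOIS_HEIGHT_EXP = 0.725


@dataclass(frozen=True)
class LayerGeometry:
    """Geometry of one phantom slice: bone areas, perimeter, muscle masses."""

    layer_index: int
    perimeter_cm: float = 0.0
    bone_cross_sections_cm2: Mapping[str, float] = field(default_factory=dict)
    muscle_masses_g: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.perimeter_cm < 0:
            raise ConfigurationError("layer perimeter must be non-negative")
        for name, area in self.bone_cross_sections_cm2.items():
            if area < 0:
                raise ConfigurationError(f"bone {name!r}: negative cross-section")
        for name, mass in self.muscle_masses_g.items():
            if mass < 0:
                raise ConfigurationError(f"muscle {name!r}: negative mass")


@dataclass(frozen=True)
class PhantomGeometry:
    """Layered phantom description with the exposed layer range."""

    layers: tuple[LayerGeometry, ...]
    layer_thickness_cm: float = 2.5
    exposed_layers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "exposed_layers", tuple(self.exposed_layers))
        if self.layer_thickness_cm <= 0:
            raise ConfigurationError("layer thickness must be positive")
        declared = {layer.layer_index for layer in self.layers}
        missing = set(self.exposed_layers) - declared
        if missing:
            raise ConfigurationError(
                f"exposed layers {sorted(missing)} not among declared layers"
            )

    def exposed(self) -> tuple[LayerGeometry, ...]:
        wanted = set(self.exposed_layers)
        return tuple(l for l in self.layers if l.layer_index in wanted)


@dataclass(frozen=True)
class ReferenceAnatomy:
    """Whole-body reference values the fraction estimators divide by.

    ``bone_surface_to_volume`` must contain one entry per exposed bone plus
    a ``"whole body"`` entry for the skeleton-wide ratio.
    ``bone_length_irradiated_fraction`` entries are free calibration
    parameters (per-bone share of the bone length inside the field).
    """

    rbm_density_g_cm3: float = 1.03
    active_marrow_share: float = 1.0 / 3.0
    total_body_bm_share_of_weight: float = 0.04
    bone_surface_to_volume_cm2_cm3: Mapping[str, float] = field(default_factory=dict)
    fresh_bone_weight_percent: Mapping[str, float] = field(default_factory=dict)
    bone_length_irradiated_fraction: Mapping[str, float] = field(default_factory=dict)
    skeleton_fresh_mass_g: float = 10500.0
    bone_density_g_cm3: float = 1.3
    total_body_muscle_mass_g: float = 28000.0
    body_mass_kg: float = 70.0
    body_height_cm: float = 180.0
    lymph_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "rbm_density_g_cm3",
            "active_marrow_share",
            "total_body_bm_share_of_weight",
            "skeleton_fresh_mass_g",
            "bone_density_g_cm3",
            "total_body_muscle_mass_g",
            "body_mass_kg",
            "body_height_cm",
            "lymph_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("active_marrow_share", "total_body_bm_share_of_weight", "lymph_fraction"):
            if getattr(self, name) > 1:
                raise ConfigurationError(f"{name} must be a fraction in (0, 1]")


def du_bois_bsa(mass_kg: float, height_cm: float) -> float:
    """Du Bois body surface area in m² from mass (kg) and height (cm)."""
    if mass_kg <= 0 or height_cm <= 0:
        raise ConfigurationError("body mass and height must be positive")
    return DU_BOIS_COEFF * mass_kg**DU_BOIS_MASS_EXP * height_cm**DU_BOIS_HEIGHT_EXP


def rbm_fraction(geometry: PhantomGeometry, anatomy: ReferenceAnatomy) -> float:
    """Red-bone-marrow fraction: exposed RBM mass over whole-body RBM mass.

    Marrow volume is the summed bone cross-section times layer thickness in
    the exposed layers; the red (active) share of it is ``active_marrow_share``
    (one third in the adult reference). The whole-body denominator applies
    the same active share to total marrow, itself 4 % of body weight.
    """
    bm_volume = 0.0
    seen_bone = False
    for layer in geometry.exposed():
        for area in layer.bone_cross_sections_cm2.values():
            bm_volume += area * geometry.layer_thickness_cm
            seen_bone = True
    if not seen_bone:
        raise ConfigurationError("no bone cross-sections in the exposed layers")
    rbm_mass = anatomy.active_marrow_share * bm_volume * anatomy.rbm_density_g_cm3
    total_bm_mass = anatomy.total_body_bm_share_of_weight * anatomy.body_mass_kg * 1000.0
    total_rbm_mass = anatomy.active_marrow_share * total_bm_mass
    return rbm_mass / total_rbm_mass


def bone_surface_fraction(
    geometry: PhantomGeometry, anatomy: ReferenceAnatomy
) -> float:
    """Exposed bone surface over whole-body bone surface.

    For each bone present in the exposed layers: whole-bone volume from its
    fresh-weight share of the skeleton, surface from the per-bone
    surface-to-volume ratio, exposed surface from the irradiated length
    fraction. The denominator applies the skeleton-wide surface-to-volume
    ratio to the whole skeleton volume.
    """
    bones = sorted(
        {name for layer in geometry.exposed() for name in layer.bone_cross_sections_cm2}
    )
    if not bones:
        raise ConfigurationError("no bones in the exposed layers")
    sv = anatomy.bone_surface_to_volume_cm2_cm3
    if "whole body" not in sv:
        raise ConfigurationError(
            "anatomy lacks the 'whole body' surface-to-volume entry"
        )
    skeleton_volume = anatomy.skeleton_fresh_mass_g / anatomy.bone_density_g_cm3
    total_surface = sv["whole body"] * skeleton_volume
    exposed_surface = 0.0
    for bone in bones:
        for table, label in (
            (sv, "surface-to-volume"),
            (anatomy.fresh_bone_weight_percent, "fresh-weight percent"),
            (anatomy.bone_length_irradiated_fraction, "irradiated length fraction"),
        ):
            if bone not in table:
                raise ConfigurationError(f"anatomy lacks {label} for bone {bone!r}")
        whole_volume = (
            anatomy.fresh_bone_weight_percent[bone]
            / 100.0
            * anatomy.skeleton_fresh_mass_g
            / anatomy.bone_density_g_cm3
        )
        exposed_surface += (
            sv[bone] * whole_volume * anatomy.bone_length_irradiated_fraction[bone]
        )
    return exposed_surface / total_surface


def skin_fraction(geometry: PhantomGeometry, anatomy: ReferenceAnatomy) -> float:
    """Exposed skin area over the Du Bois whole-body surface area."""
    exposed_area_cm2 = sum(
        layer.perimeter_cm * geometry.layer_thickness_cm for layer in geometry.exposed()
    )
    total_area_cm2 = du_bois_bsa(anatomy.body_mass_kg, anatomy.body_height_cm) * 1e4
    return exposed_area_cm2 / total_area_cm2


def muscle_fraction(geometry: PhantomGeometry, anatomy: ReferenceAnatomy) -> float:
    """Exposed muscle mass over whole-body muscle mass (28 000 g reference)."""
    exposed_mass = sum(
        mass for layer in geometry.exposed() for mass in layer.muscle_masses_g.values()
    )
    return exposed_mass / anatomy.total_body_muscle_mass_g


def lymph_fraction(anatomy: ReferenceAnatomy) -> float:
    """Configured lymphatic-node share of the whole-body lymphatic mass."""
    return anatomy.lymph_fraction


#: organ name in a tissue-map template -> fraction estimator
_ESTIMATORS = {
    "bone marrow": rbm_fraction,
    "bone surface": bone_surface_fraction,
    "skin": skin_fraction,
    "muscle": muscle_fraction,
    "lymphatic nodes": lambda geometry, anatomy: lymph_fraction(anatomy),
}


def organ_fraction_totals(
    geometry: PhantomGeometry, anatomy: ReferenceAnatomy
) -> dict[str, float]:
    """All five organ-level irradiated fractions in one mapping."""
    return {
        organ: estimator(geometry, anatomy)
        for organ, estimator in _ESTIMATORS.items()
    }


def build_tissue_map(
    geometry: PhantomGeometry,
    anatomy: ReferenceAnatomy,
    template: TissueMap,
) -> TissueMap:
    """Re-derive a tissue map's fractions from geometry and anatomy.

    The template supplies organ structure, weighting factors, dosimeter
    assignments and the per-sub-structure split of each organ total (the
    split cannot be derived from layer geometry alone, so the template's
    relative proportions are kept). Each estimated organ total is
    distributed over the template's sub-structures proportionally. Organs
    without an estimator keep their template fractions.
    """
    totals = organ_fraction_totals(geometry, anatomy)
    organs: list[OrganEntry] = []
    for organ in template.organs:
        if organ.organ not in totals:
            organs.append(organ)
            continue
        template_total = sum(sub.f_i for sub in organ.substructures)
        scale = totals[organ.organ] / template_total
        new_subs = tuple(
            replace(sub, f_i=sub.f_i * scale) for sub in organ.substructures
        )
        organs.append(replace(organ, substructures=new_subs))
    return replace(template, organs=tuple(organs))


# ---------------------------------------------------------------------------
# YAML serialisation


def geometry_from_dict(data: Mapping) -> PhantomGeometry:
    layers = tuple(
        LayerGeometry(
            layer_index=int(item["index"]),
            perimeter_cm=float(item.get("perimeter_cm", 0.0)),
            bone_cross_sections_cm2={
                str(k): float(v) for k, v in (item.get("bones") or {}).items()
            },
            muscle_masses_g={
                str(k): float(v) for k, v in (item.get("muscles") or {}).items()
            },
        )
        for item in data["layers"]
    )
    return PhantomGeometry(
        layers=layers,
        layer_thickness_cm=float(data.get("layer_thickness_cm", 2.5)),
        exposed_layers=tuple(int(i) for i in data.get("exposed_layers", ())),
    )


def anatomy_from_dict(data: Mapping) -> ReferenceAnatomy:
    kwargs = dict(data)
    for key in (
        "bone_surface_to_volume_cm2_cm3",
        "fresh_bone_weight_percent",
        "bone_length_irradiated_fraction",
    ):
        if key in kwargs:
            kwargs[key] = {str(k): float(v) for k, v in kwargs[key].items()}
    return ReferenceAnatomy(**kwargs)


def load_geometry(path) -> PhantomGeometry:
    with open(path, "r", encoding="utf-8") as fh:
        return geometry_from_dict(yaml.safe_load(fh))


def load_anatomy(path) -> ReferenceAnatomy:
    with open(path, "r", encoding="utf-8") as fh:
        return anatomy_from_dict(yaml.safe_load(fh))
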