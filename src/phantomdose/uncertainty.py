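"""Type A / type B uncertainty propagation for point-dosimetry effective doses.

All uncertainties are relative (percent, 1 SD) and assumed independent, so
they combine in quadrature. The budget has three levels:

* per dosimeter — replicate scatter (type A, the standard deviation of the
  mean of the repeated measurements) plus positioning components that act
  independently on each point measurement;
* per tissue — the per-dosimeter values propagate through the
  equivalent-dose sum as a weighted quadrature (weights = each dosimeter's
  share of H_T), and the irradiated-fraction uncertainty enters once per
  sub-structure;
* global — components coherent across all dosimeters of one exposure
  (x-ray source output variation, cable irradiation) enter once at the
  effective-dose level.

The effective-dose relative variance is the weighted sum of the per-tissue
variances, weights squared being each tissue's share of E, plus the global
terms; the expanded uncertainty uses coverage factor k = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .models import (
    ConfigurationError,
    EffectiveDoseResult,
    TissueMap,
)

VALID_SCOPES = ("per_dosimeter", "per_tissue", "global")


@dataclass(frozen=True)
class UncertaintyComponent:
    """One named relative-uncertainty component (percent, 1 SD)."""

    name: str
    relative_1sd_percent: float
    applies_to: str = "per_dosimeter"

    def __post_init__(self) -> None:
        if self.relative_1sd_percent < 0:
            raise ConfigurationError(
                f"component {self.name!r}: relative uncertainty must be >= 0"
            )
        if self.applies_to not in VALID_SCOPES:
            raise ConfigurationError(
                f"component {self.name!r}: applies_to must be one of {VALID_SCOPES}"
            )


#: Default type B budget for MOSFET phantom dosimetry: positioning acts on
#: each point measurement independently; source output and cable irradiation
#: affect the whole exposure coherently; the irradiated-fraction estimate
#: carries its own uncertainty per sub-structure.
DEFAULT_COMPONENTS: tuple[UncertaintyComponent, ...] = (
    UncertaintyComponent("dosimeter position", 10.0, "per_dosimeter"),
    UncertaintyComponent("phantom position", 10.0, "per_dosimeter"),
    UncertaintyComponent("x-ray source variation", 5.0, "global"),
    UncertaintyComponent("cable irradiation", 1.0, "global"),
    UncertaintyComponent("fraction irradiated", 25.0, "per_tissue"),
)


@dataclass(frozen=True)
class UncertaintyBudget:
    """Combined relative uncertainty of one protocol's effective dose."""

    components: tuple[UncertaintyComponent, ...]
    type_a_per_dosimeter: Mapping[int, float]
    per_tissue_1sd_percent: Mapping[str, float]
    combined_1sd_percent: float
    expanded_2sd_percent: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(
            self, "expanded_2sd_percent", 2.0 * self.combined_1sd_percent
        )


def type_a_uncertainty(
    replicates: Sequence[float], of_mean: bool = True
) -> float:
    """Relative type A uncertainty (%) from repeated measurements.

    With ``of_mean=True`` (default) this is the relative standard deviation
    of the mean, s / (mean * sqrt(n)) — the value that matters once the
    replicates have been averaged into the dose estimate. ``of_mean=False``
    gives the per-measurement relative scatter s / mean.
    """
    values = np.asarray(replicates, dtype=float)
    if values.size < 2:
        raise ConfigurationError("type A uncertainty needs at least 2 replicates")
    mean = values.mean()
    if mean <= 0:
        raise ConfigurationError("type A uncertainty undefined for non-positive mean")
    sd = values.std(ddof=1)
    if of_mean:
        sd /= math.sqrt(values.size)
    return float(100.0 * sd / mean)


def combine_quadrature(components: Iterable[float]) -> float:
    """Quadratic (root-sum-square) combination of relative uncertainties (%)."""
    values = [float(c) for c in components]
    if any(v < 0 for v in values):
        raise ConfigurationError("uncertainty components must be non-negative")
    return math.sqrt(sum(v * v for v in values))


def weighted_variance_combination(
    shares: Sequence[float], u_percent: Sequence[float]
) -> float:
    """Weighted sum of variances: sqrt(sum share_i^2 * u_i^2), shares sum to 1."""
    s = np.asarray(shares, dtype=float)
    u = np.asarray(u_percent, dtype=float)
    if s.shape != u.shape:
        raise ConfigurationError("shares and uncertainties differ in length")
    if abs(s.sum() - 1.0) > 1e-3:
        raise ConfigurationError(
            f"contribution shares must sum to 1 within 0.1%, got {s.sum():.6f}"
        )
    return float(np.sqrt(np.sum(s**2 * u**2)))


def _scope(components: Sequence[UncertaintyComponent], scope: str) -> list[float]:
    return [c.relative_1sd_percent for c in components if c.applies_to == scope]


def tissue_uncertainty(
    organ_name: str,
    tissue_map: TissueMap,
    doses_mgy: Mapping[int, float],
    type_a_percent: Mapping[int, float],
    components: Sequence[UncertaintyComponent] = DEFAULT_COMPONENTS,
) -> float:
    """Relative 1 SD uncertainty (%) of one organ's equivalent dose.

    Per-dosimeter uncertainties (type A in quadrature with the
    per-dosimeter type B components) are combined in a quadrature weighted
    by each dosimeter's share of H_T; per-tissue components (the irradiated
    fraction) enter once per sub-structure, weighted by the sub-structure's
    share of H_T.
    """
    organ = tissue_map.organ_entry(organ_name)
    per_dos_b2 = sum(c * c for c in _scope(components, "per_dosimeter"))
    per_tissue = _scope(components, "per_tissue")

    sub_terms: list[tuple[float, Sequence[int], float]] = []
    h_total = 0.0
    for sub in organ.substructures:
        sub_doses = [doses_mgy[d] for d in sub.dosimeter_ids]
        mean = sum(sub_doses) / len(sub_doses)
        h_sub = sub.f_i * mean
        h_total += h_sub
        sub_terms.append((h_sub, sub.dosimeter_ids, mean))
    if h_total <= 0:
        raise ConfigurationError(
            f"organ {organ_name!r}: uncertainty undefined for zero equivalent dose"
        )

    variance = 0.0
    for h_sub, ids, mean in sub_terms:
        n = len(ids)
        for d in ids:
            # dosimeter d's share of H_T through this sub-structure
            share = (doses_mgy[d] / n) * (h_sub / mean) / h_total
            u_d2 = type_a_percent.get(d, 0.0) ** 2 + per_dos_b2
            variance += share**2 * u_d2
        sub_share = h_sub / h_total
        variance += sub_share**2 * sum(c * c for c in per_tissue)
    return math.sqrt(variance)


def effective_dose_uncertainty(
    result: EffectiveDoseResult,
    tissue_map: TissueMap,
    doses_mgy: Mapping[int, float],
    type_a_percent: Optional[Mapping[int, float]] = None,
    components: Sequence[UncertaintyComponent] = DEFAULT_COMPONENTS,
) -> UncertaintyBudget:
    """Combined relative uncertainty budget of one protocol's effective dose."""
    type_a_percent = dict(type_a_percent or {})
    shares = result.contribution_shares()
    total_share = sum(shares.values())
    if abs(total_share - 1.0) > 1e-3:
        raise ConfigurationError(
            f"contribution shares must sum to 1 within 0.1%, got {total_share:.6f}"
        )
    per_tissue_u: dict[str, float] = {}
    variance = 0.0
    for organ in tissue_map.organs:
        share = shares.get(organ.organ, 0.0)
        if share == 0.0:
            per_tissue_u[organ.organ] = 0.0
            continue
        u_t = tissue_uncertainty(
            organ.organ, tissue_map, doses_mgy, type_a_percent, components
        )
        per_tissue_u[organ.organ] = u_t
        variance += share**2 * u_t**2
    variance += sum(c * c for c in _scope(components, "global"))
    combined = math.sqrt(variance)
    return UncertaintyBudget(
        components=tuple(components),
        type_a_per_dosimeter=type_a_percent,
        per_tissue_1sd_percent=per_tissue_u,
        combined_1sd_percent=combined,
    )


def components_from_dict(data: Mapping) -> tuple[UncertaintyComponent, ...]:
    """Parse a budget mapping: ``{components: [{name, relative_1sd_percent, applies_to}]}``."""
    return tuple(
        UncertaintyComponent(
            name=str(item["name"]),
            relative_1sd_percent=float(item["relative_1sd_percent"]),
            applies_to=str(item.get("applies_to", "per_dosimeter")),
        )
        for item in data["components"]
    )
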