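"""Domain types for phantom point-dosimetry and ICRP 103 effective dose.

The objects here mirror how an elbow (or any partial-body) dosimetry study
is organised: point dosimeters sit at named locations inside a layered
anthropomorphic phantom, each organ of interest is described by the
sub-structures the dosimeters sample together with the irradiated mass
fraction of each sub-structure, and ICRP 103 tissue weighting factors turn
per-organ equivalent doses into a single effective dose per exposure
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence


class PhantomDoseError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PhantomDoseError, ValueError):
    """A tissue map, budget or run configuration is internally inconsistent."""


class MissingDosimeterError(PhantomDoseError, KeyError):
    """An organ references a dosimeter id with no reading.

    Carries the organ name and the missing id so a user can spot the gap in
    either the readings file or the tissue map.
    """

    def __init__(self, organ: str, dosimeter_id: int):
        self.organ = organ
        self.dosimeter_id = dosimeter_id
        super().__init__(
            f"organ {organ!r} references dosimeter {dosimeter_id}, "
            "but no reading for it was supplied"
        )


class UndefinedStatisticError(PhantomDoseError, ValueError):
    """A requested statistic is undefined for the given input.

    Examples: a dose ratio against a zero baseline, or a correlation of a
    constant vector.
    """


@dataclass(frozen=True)
class DosimeterReading:
    """One absorbed-dose measurement (mGy) at a named phantom location.

    ``exposure_id`` distinguishes sub-exposures of one protocol (an AP and a
    LAT radiographic projection, say) whose doses are summed per dosimeter
    before any equivalent-dose arithmetic. ``replicate`` indexes repeated
    measurements of the same exposure; replicates are collapsed to their
    mean before dose computation, and their scatter feeds only the
    type-A uncertainty analysis.
    """

    protocol_id: str
    dosimeter_id: int
    absorbed_dose_mgy: float
    layer: int = 0
    location: str = ""
    replicate: int = 1
    exposure_id: str = "single"

    def __post_init__(self) -> None:
        if self.absorbed_dose_mgy < 0:
            raise ConfigurationError(
                f"absorbed dose must be non-negative, got {self.absorbed_dose_mgy}"
                f" (dosimeter {self.dosimeter_id}, protocol {self.protocol_id!r})"
            )
        if self.replicate < 1:
            raise ConfigurationError("replicate index must be >= 1")


@dataclass(frozen=True)
class Substructure:
    """A sub-structure of an organ: irradiated fraction plus its dosimeters.

    ``f_i`` is the irradiated mass fraction stored as a fraction
    (0.0019, not 0.19 %). The absorbed dose attributed to the sub-structure
    is the arithmetic mean over its assigned dosimeters.
    """

    name: str
    f_i: float
    dosimeter_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dosimeter_ids", tuple(self.dosimeter_ids))
        if not 0.0 < self.f_i <= 1.0:
            raise ConfigurationError(
                f"substructure {self.name!r}: irradiated fraction must be in (0, 1], "
                f"got {self.f_i}"
            )
        if len(self.dosimeter_ids) == 0:
            raise ConfigurationError(
                f"substructure {self.name!r} lists no dosimeters"
            )


@dataclass(frozen=True)
class OrganEntry:
    """An organ with its ICRP tissue weighting factor and sub-structures.

    ``is_remainder`` marks organs that share the collective ICRP 103
    remainder weight (muscle and lymphatic nodes in the elbow) rather than
    carrying ``w_t`` individually.
    """

    organ: str
    w_t: float
    is_remainder: bool
    substructures: tuple[Substructure, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "substructures", tuple(self.substructures))
        if self.w_t <= 0:
            raise ConfigurationError(
                f"organ {self.organ!r}: weighting factor must be positive, got {self.w_t}"
            )
        if len(self.substructures) == 0:
            raise ConfigurationError(f"organ {self.organ!r} has no substructures")

    @property
    def dosimeter_ids(self) -> tuple[int, ...]:
        """All dosimeter ids referenced by this organ, in substructure order."""
        out: list[int] = []
        for sub in self.substructures:
            out.extend(sub.dosimeter_ids)
        return tuple(dict.fromkeys(out))


@dataclass(frozen=True)
class TissueMap:
    """All symbols of the partial-body effective-dose model in one place.

    Holds the radiation weighting factor ``w_r`` (1 Sv/Gy for photons), the
    number of ICRP 103 remainder organs the collective remainder weight is
    shared over (13 by convention), and the organ entries with their
    irradiated fractions and dosimeter assignments.
    """

    organs: tuple[OrganEntry, ...]
    w_r: float = 1.0
    remainder_organ_count: int = 13

    def __post_init__(self) -> None:
        object.__setattr__(self, "organs", tuple(self.organs))
        if self.w_r <= 0:
            raise ConfigurationError(f"w_r must be positive, got {self.w_r}")
        if self.remainder_organ_count <= 0:
            raise ConfigurationError(
                f"remainder organ count must be positive, got {self.remainder_organ_count}"
            )
        names = [o.organ for o in self.organs]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate organ names in tissue map: {names}")

    @property
    def dosimeter_ids(self) -> tuple[int, ...]:
        out: list[int] = []
        for organ in self.organs:
            out.extend(organ.dosimeter_ids)
        return tuple(sorted(set(out)))

    def organ_entry(self, name: str) -> OrganEntry:
        for organ in self.organs:
            if organ.organ == name:
                return organ
        raise KeyError(f"organ {name!r} not in tissue map")


@dataclass(frozen=True)
class ProtocolSpec:
    """Exposure-protocol metadata (device, modality, kVp, mAs, FOV)."""

    protocol_id: str
    device: str = ""
    modality: str = "CBCT"  # radiography | MSCT | CBCT
    kvp: Optional[float] = None
    mas: Optional[float] = None
    fov: str = ""
    extra: Mapping[str, object] = field(default_factory=dict)

    _MODALITIES = ("radiography", "MSCT", "CBCT")

    def __post_init__(self) -> None:
        if self.modality not in self._MODALITIES:
            raise ConfigurationError(
                f"modality must be one of {self._MODALITIES}, got {self.modality!r}"
            )
        if self.mas is not None and self.mas <= 0:
            raise ConfigurationError(f"mAs must be positive when given, got {self.mas}")


@dataclass(frozen=True)
class EffectiveDoseResult:
    """Per-protocol effective-dose decomposition.

    ``equivalent_dose_by_organ`` holds H_T (µSv) per organ;
    ``weighted_contribution_by_organ`` holds w_T·H_T with the remainder
    weight already shared over the remainder organs, so the contributions
    sum to ``effective_dose_usv`` exactly. Percent contributions and the
    mAs-normalised dose are ``None`` when undefined (zero total dose,
    missing mAs) rather than NaN.
    """

    protocol_id: str
    equivalent_dose_by_organ: Mapping[str, float]
    weighted_contribution_by_organ: Mapping[str, float]
    effective_dose_usv: float
    contribution_percent: Optional[Mapping[str, float]]
    normalized_effective_dose: Optional[float]
    uncertainty_1sd_percent: Optional[float] = None

    def contribution_shares(self) -> Mapping[str, float]:
        """Fractional share of each organ in the effective dose."""
        if self.effective_dose_usv == 0:
            raise UndefinedStatisticError(
                f"protocol {self.protocol_id!r}: shares undefined for zero effective dose"
            )
        return {
            organ: dose / self.effective_dose_usv
            for organ, dose in self.weighted_contribution_by_organ.items()
        }


def collapse_replicates(
    readings: Sequence[DosimeterReading],
) -> dict[int, float]:
    """Collapse readings of one protocol to a per-dosimeter mean dose (mGy).

    Replicates of one exposure are averaged; distinct exposures of the same
    protocol (e.g. AP and LAT projections) are then summed per dosimeter,
    because the patient receives both.
    """
    if not readings:
        raise ConfigurationError("no readings supplied")
    protocols = {r.protocol_id for r in readings}
    if len(protocols) > 1:
        raise ConfigurationError(
            f"collapse_replicates expects one protocol, got {sorted(protocols)}"
        )
    by_exposure: dict[tuple[str, int], list[float]] = {}
    for r in readings:
        by_exposure.setdefault((r.exposure_id, r.dosimeter_id), []).append(
            r.absorbed_dose_mgy
        )
    totals: dict[int, float] = {}
    for (_, dosimeter_id), doses in by_exposure.items():
        totals[dosimeter_id] = totals.get(dosimeter_id, 0.0) + sum(doses) / len(doses)
    return totals
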