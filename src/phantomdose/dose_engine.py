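"""Equivalent dose, effective dose and derived comparison metrics.

The partial-body scheme used for extremity dosimetry weights each measured
point dose by the irradiated mass fraction of the tissue it samples:

    H_T = w_R * sum_i f_i * D_Ti          (equivalent dose of tissue T)
    E   = sum_T w_T * H_T                 (effective dose)

with D_Ti the mean absorbed dose of the dosimeters assigned to
sub-structure i, f_i its irradiated mass fraction, w_R = 1 Sv/Gy for
photons, and w_T the ICRP 103 tissue weighting factors. Remainder organs
(muscle, lymphatic nodes) share the collective remainder weight equally
over the 13 ICRP 103 remainder organs. Doses enter in mGy and equivalent/
effective doses leave in µSv (factor 1000 at w_R = 1).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .models import (
    ConfigurationError,
    DosimeterReading,
    EffectiveDoseResult,
    MissingDosimeterError,
    OrganEntry,
    ProtocolSpec,
    TissueMap,
    UndefinedStatisticError,
    collapse_replicates,
)

MGY_TO_UGY = 1000.0

DoseInput = Union[Mapping[int, float], Sequence[DosimeterReading]]


def _as_dose_map(readings: DoseInput) -> Mapping[int, float]:
    if isinstance(readings, Mapping):
        return readings
    return collapse_replicates(list(readings))


def effective_weight(organ: OrganEntry, tissue_map: TissueMap) -> float:
    """The weight actually multiplying H_T in the effective-dose sum.

    Non-remainder organs carry their own w_T; remainder organs share the
    collective remainder weight equally over ``remainder_organ_count``
    organs (13 in the ICRP 103 convention).
    """
    if organ.is_remainder:
        return organ.w_t / tissue_map.remainder_organ_count
    return organ.w_t


def equivalent_dose(
    readings: DoseInput,
    organ: OrganEntry,
    w_r: float = 1.0,
) -> float:
    """Equivalent dose H_T of one organ in µSv.

    ``readings`` is either a per-dosimeter mean dose mapping (mGy) for one
    protocol or a sequence of readings (replicates are collapsed, sub-
    exposures summed). Each sub-structure contributes f_i times the mean
    absorbed dose of its assigned dosimeters.
    """
    doses = _as_dose_map(readings)
    h_mgy = 0.0
    for sub in organ.substructures:
        try:
            sub_doses = [doses[d] for d in sub.dosimeter_ids]
        except KeyError as exc:
            raise MissingDosimeterError(organ.organ, int(exc.args[0])) from None
        h_mgy += sub.f_i * (sum(sub_doses) / len(sub_doses))
    return w_r * h_mgy * MGY_TO_UGY


def weighted_contribution(
    h_t_usv: float, organ: OrganEntry, tissue_map: TissueMap
) -> float:
    """Weighted contribution w_T·H_T (µSv), remainder-adjusted."""
    if h_t_usv < 0:
        raise ConfigurationError(f"H_T must be non-negative, got {h_t_usv}")
    return effective_weight(organ, tissue_map) * h_t_usv


def effective_dose(
    readings: DoseInput,
    tissue_map: TissueMap,
    protocol: Optional[ProtocolSpec] = None,
) -> EffectiveDoseResult:
    """Full effective-dose decomposition for one protocol.

    Returns per-organ equivalent doses, remainder-adjusted weighted
    contributions, their sum E, percent contributions (``None`` when E = 0)
    and the mAs-normalised effective dose (``None`` when the protocol
    carries no mAs).
    """
    doses = _as_dose_map(readings)
    protocol_id = protocol.protocol_id if protocol is not None else "unknown"
    if not isinstance(readings, Mapping):
        seen = {r.protocol_id for r in readings}
        if seen:
            protocol_id = seen.pop() if protocol is None else protocol_id

    h_by_organ: dict[str, float] = {}
    contribution: dict[str, float] = {}
    for organ in tissue_map.organs:
        h = equivalent_dose(doses, organ, tissue_map.w_r)
        h_by_organ[organ.organ] = h
        contribution[organ.organ] = weighted_contribution(h, organ, tissue_map)
    total = sum(contribution.values())

    percent: Optional[dict[str, float]] = None
    if total > 0:
        percent = {k: 100.0 * v / total for k, v in contribution.items()}

    normalized = None
    if protocol is not None and protocol.mas is not None:
        normalized = total / protocol.mas

    return EffectiveDoseResult(
        protocol_id=protocol_id,
        equivalent_dose_by_organ=h_by_organ,
        weighted_contribution_by_organ=contribution,
        effective_dose_usv=total,
        contribution_percent=percent,
        normalized_effective_dose=normalized,
    )


def dose_ratio_table(
    results: Iterable[EffectiveDoseResult], baseline_protocol_id: str
) -> dict[str, float]:
    """Effective dose of every protocol relative to a baseline protocol.

    The baseline maps to exactly 1.0. A zero baseline dose makes every
    ratio undefined and raises.
    """
    results = list(results)
    by_id = {r.protocol_id: r for r in results}
    if baseline_protocol_id not in by_id:
        raise KeyError(f"baseline protocol {baseline_protocol_id!r} not among results")
    baseline = by_id[baseline_protocol_id].effective_dose_usv
    if baseline == 0:
        raise UndefinedStatisticError(
            f"baseline protocol {baseline_protocol_id!r} has zero effective dose; "
            "ratios are undefined"
        )
    ratios = {
        r.protocol_id: r.effective_dose_usv / baseline for r in results
    }
    ratios[baseline_protocol_id] = 1.0
    return ratios


def mean_absorbed_dose(readings: DoseInput) -> float:
    """Arithmetic mean (mGy) over the per-dosimeter mean doses of a protocol."""
    doses = _as_dose_map(readings)
    if not doses:
        raise ConfigurationError("no doses supplied")
    return float(np.mean(list(doses.values())))


def absorbed_dose_ratio_table(
    doses_by_protocol: Mapping[str, DoseInput], baseline_protocol_id: str
) -> dict[str, float]:
    """Mean absorbed dose of every protocol relative to the baseline's mean."""
    means = {p: mean_absorbed_dose(d) for p, d in doses_by_protocol.items()}
    if baseline_protocol_id not in means:
        raise KeyError(f"baseline protocol {baseline_protocol_id!r} not among inputs")
    baseline = means[baseline_protocol_id]
    if baseline == 0:
        raise UndefinedStatisticError("baseline mean absorbed dose is zero")
    out = {p: m / baseline for p, m in means.items()}
    out[baseline_protocol_id] = 1.0
    return out


def ratio_correlation(
    effective_ratios: Sequence[float], absorbed_ratios: Sequence[float]
) -> float:
    """Pearson correlation between effective- and absorbed-dose ratio vectors."""
    x = np.asarray(effective_ratios, dtype=float)
    y = np.asarray(absorbed_ratios, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError(
            f"ratio vectors differ in length: {x.size} vs {y.size}"
        )
    if x.size < 3:
        raise ConfigurationError("need at least 3 protocols to correlate ratios")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def dose_difference_summary(
    results: Iterable[EffectiveDoseResult],
    group_a: Sequence[str],
    group_b: Sequence[str],
    background_msv_per_year: float = 3.1,
) -> dict[str, float]:
    """Mean effective dose of group A minus group B, with a background scale.

    Returns the difference in µSv and the equivalent number of days of
    natural background radiation at ``background_msv_per_year``
    (3.1 mSv/yr by default).
    """
    if not group_a or not group_b:
        raise ConfigurationError("both protocol groups must be non-empty")
    by_id = {r.protocol_id: r for r in results}
    for pid in [*group_a, *group_b]:
        if pid not in by_id:
            raise KeyError(f"protocol {pid!r} not among results")
    mean_a = float(np.mean([by_id[p].effective_dose_usv for p in group_a]))
    mean_b = float(np.mean([by_id[p].effective_dose_usv for p in group_b]))
    diff = mean_a - mean_b
    background_usv_per_day = background_msv_per_year * 1000.0 / 365.0
    return {
        "mean_a_usv": mean_a,
        "mean_b_usv": mean_b,
        "difference_usv": diff,
        "background_days": diff / background_usv_per_day,
    }
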