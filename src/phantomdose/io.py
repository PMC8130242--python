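"""Readers, writers, bundled reference data and the end-to-end pipeline.

File formats are deliberately plain: readings travel as a flat CSV (one row
per dosimeter per replicate per exposure, all protocols in one file), the
tissue map as YAML, protocol metadata as JSON. Reports are written as JSON
at full precision; rounding happens only in the rendered tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import dose_engine, uncertainty
from .fractions import (
    PhantomGeometry,
    ReferenceAnatomy,
    load_anatomy,
    load_geometry,
)
from .models import (
    ConfigurationError,
    DosimeterReading,
    EffectiveDoseResult,
    OrganEntry,
    ProtocolSpec,
    Substructure,
    TissueMap,
    UndefinedStatisticError,
    collapse_replicates,
)

log = logging.getLogger("phantomdose")

READINGS_COLUMNS = (
    "protocol_id",
    "exposure_id",
    "dosimeter_id",
    "layer",
    "location",
    "replicate",
    "absorbed_dose_mGy",
)


# ---------------------------------------------------------------------------
# readings CSV


def read_readings(path) -> list[DosimeterReading]:
    """Read a readings CSV into validated records.

    Requires the header ``protocol_id, exposure_id, dosimeter_id, layer,
    location, replicate, absorbed_dose_mGy``; duplicate (protocol,
    exposure, dosimeter, replicate) rows and malformed values are rejected
    with their line numbers.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ConfigurationError(f"readings file {path} is empty") from None
    missing = [c for c in ("protocol_id", "dosimeter_id", "absorbed_dose_mGy") if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"readings file {path} lacks columns {missing}")
    if frame.empty:
        raise ConfigurationError(f"readings file {path} contains no rows")
    readings: list[DosimeterReading] = []
    seen: set[tuple] = set()
    for idx, row in frame.iterrows():
        line = idx + 2  # header on line 1
        try:
            reading = DosimeterReading(
                protocol_id=str(row["protocol_id"]),
                exposure_id=str(row.get("exposure_id", "single")),
                dosimeter_id=int(row["dosimeter_id"]),
                layer=int(row.get("layer", 0)),
                location=str(row.get("location", "")),
                replicate=int(row.get("replicate", 1)),
                absorbed_dose_mgy=float(row["absorbed_dose_mGy"]),
            )
        except (ValueError, TypeError, ConfigurationError) as exc:
            raise ConfigurationError(f"{path} line {line}: {exc}") from None
        key = (
            reading.protocol_id,
            reading.exposure_id,
            reading.dosimeter_id,
            reading.replicate,
        )
        if key in seen:
            raise ConfigurationError(
                f"{path} line {line}: duplicate reading for {key}"
            )
        seen.add(key)
        readings.append(reading)
    return readings


def readings_to_frame(readings: Sequence[DosimeterReading]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protocol_id": [r.protocol_id for r in readings],
            "exposure_id": [r.exposure_id for r in readings],
            "dosimeter_id": [r.dosimeter_id for r in readings],
            "layer": [r.layer for r in readings],
            "location": [r.location for r in readings],
            "replicate": [r.replicate for r in readings],
            "absorbed_dose_mGy": [r.absorbed_dose_mgy for r in readings],
        }
    )


def write_readings(readings: Sequence[DosimeterReading], path) -> None:
    readings_to_frame(readings).to_csv(path, index=False)


def split_by_protocol(
    readings: Sequence[DosimeterReading],
) -> dict[str, list[DosimeterReading]]:
    """Group readings by protocol, preserving first-appearance order."""
    out: dict[str, list[DosimeterReading]] = {}
    for r in readings:
        out.setdefault(r.protocol_id, []).append(r)
    return out


# ---------------------------------------------------------------------------
# tissue map YAML


def tissue_map_from_dict(data: Mapping) -> TissueMap:
    organs = tuple(
        OrganEntry(
            organ=str(o["organ"]),
            w_t=float(o["w_T"]),
            is_remainder=bool(o["is_remainder"]),
            substructures=tuple(
                Substructure(
                    name=str(s["name"]),
                    f_i=float(s["f_i"]),
                    dosimeter_ids=tuple(int(d) for d in s["dosimeters"]),
                )
                for s in o["substructures"]
            ),
        )
        for o in data["organs"]
    )
    return TissueMap(
        organs=organs,
        w_r=float(data.get("w_R", 1.0)),
        remainder_organ_count=int(data.get("remainder_organ_count", 13)),
    )


def tissue_map_to_dict(tissue_map: TissueMap) -> dict:
    return {
        "w_R": tissue_map.w_r,
        "remainder_organ_count": tissue_map.remainder_organ_count,
        "organs": [
            {
                "organ": o.organ,
                "w_T": o.w_t,
                "is_remainder": o.is_remainder,
                "substructures": [
                    {
                        "name": s.name,
                        "f_i": s.f_i,
                        "dosimeters": list(s.dosimeter_ids),
                    }
                    for s in o.substructures
                ],
            }
            for o in tissue_map.organs
        ],
    }


def load_tissue_map(path) -> TissueMap:
    with open(path, "r", encoding="utf-8") as fh:
        return tissue_map_from_dict(yaml.safe_load(fh))


def dump_tissue_map(tissue_map: TissueMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(tissue_map_to_dict(tissue_map), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# protocols JSON


def protocols_from_dict(data: Mapping) -> dict[str, ProtocolSpec]:
    out: dict[str, ProtocolSpec] = {}
    for item in data["protocols"]:
        spec = ProtocolSpec(
            protocol_id=str(item["protocol_id"]),
            device=str(item.get("device", "")),
            modality=str(item.get("modality", "CBCT")),
            kvp=None if item.get("kVp") is None else float(item["kVp"]),
            mas=None if item.get("mAs") is None else float(item["mAs"]),
            fov=str(item.get("fov", "")),
            extra=dict(item.get("extra", {})),
        )
        out[spec.protocol_id] = spec
    return out


def load_protocols(path) -> dict[str, ProtocolSpec]:
    with open(path, "r", encoding="utf-8") as fh:
        return protocols_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# bundled reference data (the measured elbow-phantom study)


def _data_path(name: str):
    return resources.files("phantomdose.data").joinpath(name)


def load_reference_readings() -> list[DosimeterReading]:
    """Measured absorbed doses: 11 dosimeters x 7 protocols, one replicate."""
    with resources.as_file(_data_path("elbow_readings.csv")) as path:
        return read_readings(path)


def load_reference_tissue_map() -> TissueMap:
    """ICRP 103 elbow tissue map: fractions, weights, dosimeter assignments."""
    with resources.as_file(_data_path("icrp103_elbow.yaml")) as path:
        return load_tissue_map(path)


def load_reference_protocols() -> dict[str, ProtocolSpec]:
    """Exposure parameters of the seven protocols (kVp, mAs, FOV, indices)."""
    with resources.as_file(_data_path("elbow_protocols.json")) as path:
        return load_protocols(path)


def load_reference_budget() -> tuple:
    """Default type B uncertainty components."""
    with resources.as_file(_data_path("uncertainty_budget.yaml")) as path:
        with open(path, "r", encoding="utf-8") as fh:
            return uncertainty.components_from_dict(yaml.safe_load(fh))


def load_calibration_geometry() -> PhantomGeometry:
    """Synthetic elbow-phantom geometry calibrated to the study's organ totals."""
    with resources.as_file(_data_path("elbow_geometry_synthetic.yaml")) as path:
        return load_geometry(path)


def load_reference_anatomy() -> ReferenceAnatomy:
    """Reference-anatomy constants feeding the fraction estimators."""
    with resources.as_file(_data_path("reference_anatomy_synthetic.yaml")) as path:
        return load_anatomy(path)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    readings_path: Path
    tissue_map_path: Path
    protocols_path: Path
    budget_path: Optional[Path] = None
    baseline_protocol_id: Optional[str] = None
    rounding: int = 1
    background_msv_per_year: float = 3.1

    def __post_init__(self) -> None:
        if self.rounding < 0:
            raise ConfigurationError("rounding must be >= 0 decimals")
        for attr in ("readings_path", "tissue_map_path", "protocols_path", "budget_path"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{attr} does not exist: {value}")


def _protocol_uncertainty(
    readings: Sequence[DosimeterReading],
    result: EffectiveDoseResult,
    tissue_map: TissueMap,
    doses: Mapping[int, float],
    components,
) -> Optional[uncertainty.UncertaintyBudget]:
    """Type A from replicate scatter when replicates exist, else type B only."""
    by_dosimeter: dict[int, list[float]] = {}
    for r in readings:
        by_dosimeter.setdefault(r.dosimeter_id, []).append(r.absorbed_dose_mgy)
    type_a = {
        d: uncertainty.type_a_uncertainty(vals)
        for d, vals in by_dosimeter.items()
        if len(vals) >= 2 and sum(vals) > 0
    }
    if result.effective_dose_usv == 0:
        return None
    return uncertainty.effective_dose_uncertainty(
        result, tissue_map, doses, type_a, components
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return a JSON-serialisable report.

    Stages: read inputs, compute per-protocol effective doses, dose ratios
    against the baseline (default: the radiography protocol), the Pearson
    correlation of effective- vs absorbed-dose ratio vectors, the
    MSCT-vs-CBCT mean dose difference expressed in days of background
    radiation, and (when a budget is configured) per-protocol uncertainty
    budgets.
    """
    log.info("[read] loading inputs")
    readings = read_readings(config.readings_path)
    tissue_map = load_tissue_map(config.tissue_map_path)
    protocols = load_protocols(config.protocols_path)
    components = uncertainty.DEFAULT_COMPONENTS
    if config.budget_path is not None:
        with open(config.budget_path, "r", encoding="utf-8") as fh:
            components = uncertainty.components_from_dict(yaml.safe_load(fh))

    by_protocol = split_by_protocol(readings)
    unknown = set(by_protocol) - set(protocols)
    if unknown:
        raise ConfigurationError(
            f"[read] readings reference protocols missing from metadata: {sorted(unknown)}"
        )
    ordered = [p for p in protocols if p in by_protocol]

    log.info("[dose] computing effective doses for %d protocols", len(ordered))
    results: dict[str, EffectiveDoseResult] = {}
    doses_by_protocol: dict[str, Mapping[int, float]] = {}
    budgets: dict[str, Optional[uncertainty.UncertaintyBudget]] = {}
    for pid in ordered:
        doses = collapse_replicates(by_protocol[pid])
        doses_by_protocol[pid] = doses
        result = dose_engine.effective_dose(doses, tissue_map, protocols[pid])
        result = EffectiveDoseResult(
            protocol_id=pid,
            equivalent_dose_by_organ=result.equivalent_dose_by_organ,
            weighted_contribution_by_organ=result.weighted_contribution_by_organ,
            effective_dose_usv=result.effective_dose_usv,
            contribution_percent=result.contribution_percent,
            normalized_effective_dose=result.normalized_effective_dose,
        )
        results[pid] = result
        if result.effective_dose_usv == 0:
            log.warning("[dose] protocol %s: zero effective dose", pid)
        budgets[pid] = _protocol_uncertainty(
            by_protocol[pid], result, tissue_map, doses, components
        )

    baseline = config.baseline_protocol_id
    if baseline is None:
        radiography = [p for p in ordered if protocols[p].modality == "radiography"]
        baseline = radiography[0] if radiography else ordered[0]

    log.info("[metrics] ratios, correlation and group differences")
    effective_ratios = absorbed_ratios = None
    correlation = None
    try:
        effective_ratios = dose_engine.dose_ratio_table(results.values(), baseline)
        absorbed_ratios = dose_engine.absorbed_dose_ratio_table(
            doses_by_protocol, baseline
        )
        correlation = dose_engine.ratio_correlation(
            [effective_ratios[p] for p in ordered],
            [absorbed_ratios[p] for p in ordered],
        )
    except (UndefinedStatisticError, ConfigurationError) as exc:
        log.warning("[metrics] ratio statistics unavailable: %s", exc)

    msct = [p for p in ordered if protocols[p].modality == "MSCT"]
    cbct = [p for p in ordered if protocols[p].modality == "CBCT"]
    comparison = None
    if msct and cbct:
        summary = dose_engine.dose_difference_summary(
            results.values(), msct, cbct, config.background_msv_per_year
        )
        comparison = {"group_a": msct, "group_b": cbct, **summary}

    report = {
        "baseline_protocol_id": baseline,
        "background_msv_per_year": config.background_msv_per_year,
        "rounding": config.rounding,
        "protocols": {
            pid: {
                "device": protocols[pid].device,
                "modality": protocols[pid].modality,
                "kVp": protocols[pid].kvp,
                "mAs": protocols[pid].mas,
                "fov": protocols[pid].fov,
            }
            for pid in ordered
        },
        "results": {
            pid: _result_to_dict(results[pid], doses_by_protocol[pid], budgets[pid])
            for pid in ordered
        },
        "effective_dose_ratios": effective_ratios,
        "absorbed_dose_ratios": absorbed_ratios,
        "ratio_correlation": correlation,
        "modality_comparison": comparison,
    }
    return report


def _result_to_dict(
    result: EffectiveDoseResult,
    doses: Mapping[int, float],
    budget: Optional[uncertainty.UncertaintyBudget],
) -> dict:
    out = {
        "equivalent_dose_by_organ_usv": dict(result.equivalent_dose_by_organ),
        "weighted_contribution_by_organ_usv": dict(
            result.weighted_contribution_by_organ
        ),
        "effective_dose_usv": result.effective_dose_usv,
        "contribution_percent": (
            dict(result.contribution_percent)
            if result.contribution_percent is not None
            else None
        ),
        "normalized_effective_dose_usv_per_mas": result.normalized_effective_dose,
        "absorbed_dose_by_dosimeter_mgy": {str(k): v for k, v in sorted(doses.items())},
        "mean_absorbed_dose_mgy": dose_engine.mean_absorbed_dose(doses),
        "uncertainty": None,
    }
    if budget is not None:
        out["uncertainty"] = {
            "combined_1sd_percent": budget.combined_1sd_percent,
            "expanded_2sd_percent": budget.expanded_2sd_percent,
            "per_tissue_1sd_percent": dict(budget.per_tissue_1sd_percent),
            "type_a_per_dosimeter_percent": {
                str(k): v for k, v in sorted(budget.type_a_per_dosimeter.items())
            },
        }
    return out


def write_report(report: Mapping, path) -> None:
    """Write the full-precision JSON report, validating serialisability."""
    text = json.dumps(report, indent=2, allow_nan=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# rendered tables


def render_tables(report: Mapping) -> dict[str, pd.DataFrame]:
    """Round the report into the two publication-style comparison tables.

    ``effective_doses``: weighted per-organ contributions per protocol with
    effective dose, mAs-normalised dose and baseline-relative ratio rows.
    ``absorbed_doses``: per-dosimeter doses with average-dose and ratio rows.
    """
    rounding = int(report.get("rounding", 1))
    protocols = list(report["results"].keys())
    organ_names: list[str] = []
    for pid in protocols:
        for organ in report["results"][pid]["weighted_contribution_by_organ_usv"]:
            if organ not in organ_names:
                organ_names.append(organ)

    eff_rows: dict[str, list] = {organ: [] for organ in organ_names}
    eff_rows["Effective dose"] = []
    eff_rows["Norm.E (uSv/mAs)"] = []
    eff_rows["Effective dose ratio"] = []
    for pid in protocols:
        res = report["results"][pid]
        for organ in organ_names:
            value = res["weighted_contribution_by_organ_usv"].get(organ)
            eff_rows[organ].append(
                None if value is None else round(value, rounding)
            )
        eff_rows["Effective dose"].append(round(res["effective_dose_usv"], rounding))
        norm = res["normalized_effective_dose_usv_per_mas"]
        eff_rows["Norm.E (uSv/mAs)"].append(
            None if norm is None else round(norm, rounding + 1)
        )
        ratios = report.get("effective_dose_ratios")
        eff_rows["Effective dose ratio"].append(
            None if ratios is None else round(ratios[pid], rounding)
        )
    effective = pd.DataFrame(eff_rows, index=protocols).T
    effective.columns.name = "protocol"

    dosimeters: list[str] = []
    for pid in protocols:
        for d in report["results"][pid]["absorbed_dose_by_dosimeter_mgy"]:
            if d not in dosimeters:
                dosimeters.append(d)
    dosimeters.sort(key=int)
    abs_rows: dict[str, list] = {d: [] for d in dosimeters}
    abs_rows["Average dose"] = []
    abs_rows["Absorbed dose ratio"] = []
    for pid in protocols:
        res = report["results"][pid]
        for d in dosimeters:
            value = res["absorbed_dose_by_dosimeter_mgy"].get(d)
            abs_rows[d].append(None if value is None else round(value, rounding))
        abs_rows["Average dose"].append(round(res["mean_absorbed_dose_mgy"], rounding))
        ratios = report.get("absorbed_dose_ratios")
        abs_rows["Absorbed dose ratio"].append(
            None if ratios is None else round(ratios[pid], rounding)
        )
    absorbed = pd.DataFrame(abs_rows, index=protocols).T
    absorbed.columns.name = "protocol"
    absorbed.index.name = "dosimeter"
    return {"effective_doses": effective, "absorbed_doses": absorbed}
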