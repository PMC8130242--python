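"""Equivalent/effective dose engine against oracles, examples and invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomdose import (
    absorbed_dose_ratio_table,
    dose_difference_summary,
    dose_ratio_table,
    effective_dose,
    equivalent_dose,
    mean_absorbed_dose,
    ratio_correlation,
    weighted_contribution,
)
from phantomdose.models import (
    ConfigurationError,
    EffectiveDoseResult,
    MissingDosimeterError,
    OrganEntry,
    Substructure,
    TissueMap,
    UndefinedStatisticError,
)

from conftest import (
    PUBLISHED_EFFECTIVE_DOSE,
    oracle_effective_dose_usv,
    oracle_equivalent_dose_usv,
)


def _result(pid: str, e: float) -> EffectiveDoseResult:
    return EffectiveDoseResult(
        protocol_id=pid,
        equivalent_dose_by_organ={},
        weighted_contribution_by_organ={"all": e},
        effective_dose_usv=e,
        contribution_percent=None,
        normalized_effective_dose=None,
    )


# --- random small tissue maps + dose fields for property tests -------------

@st.composite
def tissue_map_and_doses(draw):
    n_dosimeters = draw(st.integers(min_value=1, max_value=11))
    ids = list(range(1, n_dosimeters + 1))
    organs = []
    n_organs = draw(st.integers(min_value=1, max_value=5))
    for i in range(n_organs):
        n_subs = draw(st.integers(min_value=1, max_value=3))
        subs = tuple(
            Substructure(
                name=f"sub{i}_{j}",
                f_i=draw(st.floats(min_value=1e-4, max_value=1.0)),
                dosimeter_ids=tuple(
                    draw(
                        st.lists(
                            st.sampled_from(ids), min_size=1, max_size=4, unique=True
                        )
                    )
                ),
            )
            for j in range(n_subs)
        )
        organs.append(
            OrganEntry(
                organ=f"organ{i}",
                w_t=draw(st.floats(min_value=0.01, max_value=0.2)),
                is_remainder=draw(st.booleans()),
                substructures=subs,
            )
        )
    tm = TissueMap(organs=tuple(organs))
    doses = {
        d: draw(st.floats(min_value=0.0, max_value=50.0)) for d in ids
    }
    return tm, doses


@settings(max_examples=60, deadline=None, derandomize=True)
@given(tissue_map_and_doses())
def test_engine_matches_exhaustive_oracle(case):
    """The engine equals term-by-term summation on random small tissue maps."""
    tm, doses = case
    for organ in tm.organs:
        got = equivalent_dose(doses, organ, tm.w_r)
        want = oracle_equivalent_dose_usv(doses, organ, tm.w_r)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)
    result = effective_dose(doses, tm)
    assert result.effective_dose_usv == pytest.approx(
        oracle_effective_dose_usv(doses, tm), rel=1e-9, abs=1e-12
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(tissue_map_and_doses(), st.floats(min_value=0.1, max_value=20.0))
def test_linearity_in_readings(case, scale):
    """Scaling all doses by c scales every H_T, contribution and E by c."""
    tm, doses = case
    base = effective_dose(doses, tm)
    scaled = effective_dose({d: v * scale for d, v in doses.items()}, tm)
    assert scaled.effective_dose_usv == pytest.approx(
        base.effective_dose_usv * scale, rel=1e-9, abs=1e-12
    )
    for organ in tm.organs:
        assert scaled.equivalent_dose_by_organ[organ.organ] == pytest.approx(
            base.equivalent_dose_by_organ[organ.organ] * scale, rel=1e-9, abs=1e-12
        )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(tissue_map_and_doses(), st.floats(min_value=0.01, max_value=10.0))
def test_monotonicity_in_single_reading(case, bump):
    """Increasing any single reading never decreases the effective dose."""
    tm, doses = case
    base = effective_dose(doses, tm).effective_dose_usv
    for d in doses:
        bumped = dict(doses)
        bumped[d] += bump
        assert effective_dose(bumped, tm).effective_dose_usv >= base - 1e-12


@settings(max_examples=40, deadline=None, derandomize=True)
@given(tissue_map_and_doses())
def test_conservation_of_weighted_contributions(case):
    """Weighted contributions sum to the effective dose to 1e-9 relative."""
    tm, doses = case
    result = effective_dose(doses, tm)
    total = sum(result.weighted_contribution_by_organ.values())
    assert total == pytest.approx(result.effective_dose_usv, rel=1e-9, abs=1e-15)
    if result.contribution_percent is not None:
        assert sum(result.contribution_percent.values()) == pytest.approx(100.0, abs=0.1)


# --- worked examples -------------------------------------------------------

def test_equivalent_dose_examples(tissue_map, dose_maps):
    """Lymph nodes under MSCT, the identity case, and the all-zero case."""
    lymph = tissue_map.organ_entry("lymphatic nodes")
    # 5% of the 18.5 mGy cubital-node dose = 0.925 mGy = 925 µSv
    assert equivalent_dose(dose_maps["siemens_msct"], lymph) == pytest.approx(925.0)
    assert equivalent_dose({6: 0.0}, lymph) == 0.0
    identity = OrganEntry(
        "o", 0.1, False, (Substructure("s", 1.0, (1,)),)
    )
    assert equivalent_dose({1: 1.0}, identity) == pytest.approx(1000.0)


def test_msct_muscle_equivalent_dose_frozen_oracle_value(tissue_map, dose_maps):
    """Five-term muscle sum under MSCT, frozen from a term-by-term evaluation.

    0.0004*19.3 + 0.0005*18.5 + 0.0018*18.5 + 0.0022*21.6 + 0.0040*18.8
    = 0.17299 mGy.
    """
    muscle = tissue_map.organ_entry("muscle")
    got = equivalent_dose(dose_maps["siemens_msct"], muscle)
    assert got == pytest.approx(172.99, rel=1e-9)


def test_weighted_contribution_remainder_rule(tissue_map, dose_maps):
    """The w/13 remainder convention reproduces the published lymph and muscle rows."""
    lymph = tissue_map.organ_entry("lymphatic nodes")
    muscle = tissue_map.organ_entry("muscle")
    doses = dose_maps["siemens_msct"]
    lymph_c = weighted_contribution(equivalent_dose(doses, lymph), lymph, tissue_map)
    muscle_c = weighted_contribution(equivalent_dose(doses, muscle), muscle, tissue_map)
    assert lymph_c == pytest.approx(8.5, abs=0.1)
    assert muscle_c == pytest.approx(1.6, abs=0.1)
    # direct product for a non-remainder organ
    plain = OrganEntry("o", 0.12, False, (Substructure("s", 0.5, (1,)),))
    assert weighted_contribution(100.0, plain, tissue_map) == pytest.approx(12.0)


def test_effective_dose_reproduces_published_values(tissue_map, protocols, dose_maps):
    """All seven published effective doses are reproduced within 10 %."""
    for pid, expected in PUBLISHED_EFFECTIVE_DOSE.items():
        result = effective_dose(dose_maps[pid], tissue_map, protocols[pid])
        assert result.effective_dose_usv == pytest.approx(expected, rel=0.10), pid


def test_msct_bone_marrow_share(tissue_map, dose_maps):
    """Bone marrow dominates the MSCT effective dose at about half of it."""
    result = effective_dose(dose_maps["siemens_msct"], tissue_map)
    share = result.contribution_percent["bone marrow"]
    assert share == pytest.approx(51.0, abs=2.0)


def test_zero_readings_give_zero_doses_and_absent_percentages(tissue_map):
    doses = {d: 0.0 for d in tissue_map.dosimeter_ids}
    result = effective_dose(doses, tissue_map)
    assert result.effective_dose_usv == 0.0
    assert all(v == 0.0 for v in result.weighted_contribution_by_organ.values())
    assert result.contribution_percent is None
    with pytest.raises(UndefinedStatisticError):
        result.contribution_shares()


def test_missing_dosimeter_error_names_organ_and_id(tissue_map):
    doses = {d: 1.0 for d in tissue_map.dosimeter_ids if d != 6}
    with pytest.raises(MissingDosimeterError) as err:
        effective_dose(doses, tissue_map)
    assert err.value.dosimeter_id == 6
    assert err.value.organ


def test_normalized_dose_absent_without_mas(tissue_map, dose_maps):
    from phantomdose.models import ProtocolSpec

    protocol = ProtocolSpec(protocol_id="p", modality="CBCT", mas=None)
    result = effective_dose(dose_maps["planmed_verity"], tissue_map, protocol)
    assert result.normalized_effective_dose is None


# --- derived metrics -------------------------------------------------------

def test_mean_absorbed_dose_examples(dose_maps):
    """Published MSCT column averages to 16.1 mGy; constants are fixed points."""
    column = dose_maps["siemens_msct"]
    assert mean_absorbed_dose(column) == pytest.approx(
        sum(column.values()) / len(column)
    )
    assert round(mean_absorbed_dose(column), 1) == 16.1
    assert mean_absorbed_dose({1: 3.3, 2: 3.3}) == pytest.approx(3.3)
    with pytest.raises(ConfigurationError):
        mean_absorbed_dose({})


def test_dose_ratio_table_identity_and_oracle():
    results = [_result("a", 2.0), _result("b", 5.0), _result("c", 0.5)]
    ratios = dose_ratio_table(results, "a")
    assert ratios["a"] == 1.0
    assert ratios["b"] == pytest.approx(5.0 / 2.0)
    assert ratios["c"] == pytest.approx(0.5 / 2.0)
    with pytest.raises(UndefinedStatisticError):
        dose_ratio_table([_result("a", 0.0), _result("b", 1.0)], "a")
    with pytest.raises(KeyError):
        dose_ratio_table(results, "nope")


def test_published_hires_vs_standard_ratio():
    """On the published effective doses the HiRes/Standard ratio is ~3.4."""
    results = [_result(p, e) for p, e in PUBLISHED_EFFECTIVE_DOSE.items()]
    ratios = dose_ratio_table(results, "newtom_standard_12x8")
    assert ratios["newtom_hires_12x8"] == pytest.approx(3.4, abs=0.1)


def test_ratio_correlation_against_textbook_formula():
    rng = np.random.default_rng(11)
    x = rng.uniform(0.5, 30, size=7)
    y = x * 1.1 + rng.normal(0, 1, size=7)
    got = ratio_correlation(x, y)
    # independent direct evaluation of the product-moment formula
    xm, ym = x - x.mean(), y - y.mean()
    want = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
    assert got == pytest.approx(want, abs=1e-12)
    assert ratio_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    with pytest.raises(UndefinedStatisticError):
        ratio_correlation([1, 1, 1], [1, 2, 3])
    with pytest.raises(ConfigurationError):
        ratio_correlation([1, 2], [1, 2])


def test_correlation_invariant_to_baseline_choice(tissue_map, dose_maps, protocols):
    """Pearson correlation of ratio vectors ignores the (positive) baseline."""
    results = [
        effective_dose(dose_maps[p], tissue_map, protocols[p]) for p in dose_maps
    ]
    corr = {}
    for baseline in ("shimadzu_radiography", "siemens_msct"):
        eff = dose_ratio_table(results, baseline)
        absr = absorbed_dose_ratio_table(dose_maps, baseline)
        order = list(dose_maps)
        corr[baseline] = ratio_correlation(
            [eff[p] for p in order], [absr[p] for p in order]
        )
    assert corr["shimadzu_radiography"] == pytest.approx(
        corr["siemens_msct"], abs=1e-12
    )


def test_dose_difference_summary_examples():
    """MSCT-vs-CBCT difference on published doses: ~34.2 µSv, ~4 background days."""
    results = [_result(p, e) for p, e in PUBLISHED_EFFECTIVE_DOSE.items()]
    cbct = [
        "newtom_hires_12x8",
        "newtom_standard_12x8",
        "newtom_standard_15x12",
        "newtom_standard_18x16",
        "planmed_verity",
    ]
    summary = dose_difference_summary(results, ["siemens_msct"], cbct)
    assert summary["difference_usv"] == pytest.approx(34.2, abs=0.05)
    assert summary["background_days"] == pytest.approx(4.0, abs=0.1)
    same = dose_difference_summary(results, cbct, cbct)
    assert same["difference_usv"] == 0.0
    with pytest.raises(KeyError):
        dose_difference_summary(results, ["siemens_msct"], ["nope"])
    with pytest.raises(ConfigurationError):
        dose_difference_summary(results, [], cbct)
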