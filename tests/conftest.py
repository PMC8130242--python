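"""Shared fixtures: the measured elbow study and independent oracles."""

from __future__ import annotations

import pytest

from phantomdose import reference_dataset
from phantomdose.io import split_by_protocol
from phantomdose.models import TissueMap, collapse_replicates

#: Printed effective doses (µSv) of the seven protocols, used as published
#: comparison values and, where a metric is defined on published results,
#: as inputs.
PUBLISHED_EFFECTIVE_DOSE = {
    "shimadzu_radiography": 1.5,
    "siemens_msct": 37.4,
    "newtom_hires_12x8": 6.7,
    "newtom_standard_12x8": 2.0,
    "newtom_standard_15x12": 2.5,
    "newtom_standard_18x16": 2.1,
    "planmed_verity": 2.6,
}


@pytest.fixture(scope="session")
def study():
    """(readings, tissue_map, protocols) of the measured elbow study."""
    return reference_dataset()


@pytest.fixture(scope="session")
def tissue_map(study) -> TissueMap:
    return study[1]


@pytest.fixture(scope="session")
def protocols(study):
    return study[2]


@pytest.fixture(scope="session")
def dose_maps(study):
    """Per-protocol {dosimeter: mean absorbed dose (mGy)} mappings."""
    readings, _, _ = study
    return {
        pid: collapse_replicates(rs)
        for pid, rs in split_by_protocol(readings).items()
    }


def oracle_equivalent_dose_usv(doses, organ, w_r=1.0):
    """Independent exhaustive term-by-term evaluation of H_T (µSv).

    Deliberately naive: explicit loops, no shared code with the engine.
    """
    total = 0.0
    for sub in organ.substructures:
        acc = 0.0
        for d in sub.dosimeter_ids:
            acc += doses[d]
        total += sub.f_i * acc / len(sub.dosimeter_ids)
    return w_r * total * 1000.0


def oracle_effective_dose_usv(doses, tissue_map):
    """Independent effective dose: weighted sum over organs (µSv)."""
    total = 0.0
    for organ in tissue_map.organs:
        h = oracle_equivalent_dose_usv(doses, organ, tissue_map.w_r)
        w = organ.w_t / tissue_map.remainder_organ_count if organ.is_remainder else organ.w_t
        total += w * h
    return total
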