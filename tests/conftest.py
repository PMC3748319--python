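from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from phloemkey import (
    CCLabel,
    DivisionPlane,
    SECCCSlot,
    SlotPosition,
    Symmetry,
    Tristate,
    VeinObservation,
    canonical_profile,
    worked_example_expectations,
    worked_example_records,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked_records():
    return worked_example_records()


@pytest.fixture(scope="session")
def worked_expected():
    return worked_example_expectations()


def make_slot(label: CCLabel, n_cc: int = 1, se: int = 1,
              pos: SlotPosition = SlotPosition.UNSPECIFIED) -> SECCCSlot:
    return SECCCSlot(cc_profiles=(canonical_profile(label),) * n_cc,
                     se_count=se, position=pos)


def type1_vein(*slots: SECCCSlot) -> VeinObservation:
    return VeinObservation(
        slots=slots,
        spatial_symmetry=Symmetry.WELL_DEFINED,
        phloem_parenchyma_present=Tristate.NO,
        pp_cwi_present=Tristate.NO,
        vascular_parenchyma_row_present=Tristate.YES,
        first_division_plane=DivisionPlane.ANTICLINAL,
    )


def type2_vein(*slots: SECCCSlot, pp_cwi: Tristate = Tristate.NO,
               symmetry: Symmetry = Symmetry.WELL_DEFINED) -> VeinObservation:
    return VeinObservation(
        slots=slots,
        spatial_symmetry=symmetry,
        phloem_parenchyma_present=Tristate.YES,
        pp_cwi_present=pp_cwi,
        vascular_parenchyma_row_present=Tristate.NO,
        first_division_plane=DivisionPlane.PERICLINAL,
    )
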