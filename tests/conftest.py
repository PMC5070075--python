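import numpy as np
import pytest

from dpmkit.core import (
    CaseMetadata,
    Cue,
    CueSource,
    DecisionProcessMatrix,
    OptionTrack,
    Outcome,
    Unit,
    UnitKind,
)
from dpmkit.examples import worked_example
from dpmkit.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def example():
    """The packaged 46-unit worked example."""
    return worked_example()


def build_minimal_case(case_id: str = "mini") -> DecisionProcessMatrix:
    """Smallest conforming case: cue, option, confidence, final."""
    return DecisionProcessMatrix(
        metadata=CaseMetadata(case_id=case_id, resident_id="R1"),
        units=(
            Unit(1, UnitKind.CUE, ref_id="c1"),
            Unit(2, UnitKind.OPTION, ref_id="o1"),
            Unit(3, UnitKind.CONFIDENCE, option_ref="o1", cue_ref="c1", level=2),
            Unit(4, UnitKind.FINAL, option_ref=("o1",)),
        ),
        cues=(Cue("c1", "presenting complaint", CueSource.MHT),),
        options=(OptionTrack("o1", "working diagnosis", Outcome.FINAL),),
    )


@pytest.fixture
def minimal_case():
    return build_minimal_case()


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """300 generated cases shared by the property-style tests."""
    import dataclasses

    cfg = dataclasses.replace(default_config, n_cases=300)
    cases, _ = generate_cohort(cfg, seed=20161018)
    return cases
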