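import numpy as np
import pytest

import skitech as sk
from skitech import synthetic as syn


@pytest.fixture(scope="session")
def templates():
    return syn.default_templates()


@pytest.fixture(scope="session")
def small_recording():
    """One subject, two classical techniques, 10 rendered cycles each."""
    plan = syn.SimPlan((syn.FileRecipe("S1", "flat", "classical", ((1, 10), (4, 10))),))
    rec, track, bounds = syn.generate_dataset(plan, seed=3)[0]
    return rec, track, bounds


@pytest.fixture(scope="session")
def small_cycles(small_recording):
    rec, track, _ = small_recording
    return sk.segment_recording(rec, track, source="small")


@pytest.fixture(scope="session")
def default_cycles():
    """The shipped 3-subject study design, dataset seed 1 (~420 cycles)."""
    return syn.build_cycles(syn.default_plan(3, 12), seed=1)
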