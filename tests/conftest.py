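import pytest

from tc1scout.synthetic_genome import ElementSpec, PlantPlan, TriadSpec


@pytest.fixture
def small_spec() -> ElementSpec:
    """A compact element (1,453 bp) that keeps alignment-heavy tests fast."""
    return ElementSpec(
        tir_len=50, utr5_len=60, orf_len=1203, utr3_len=90,
        triad=TriadSpec(30, 250, "E", 40),
    )


@pytest.fixture
def op1_spec() -> ElementSpec:
    """The full-size five-segment geometry of the large yeast element."""
    return ElementSpec(
        tir_len=169, utr5_len=245, orf_len=3468, utr3_len=1608,
        triad=TriadSpec(892, 1056, "E", 40),
    )


@pytest.fixture
def basic_plan() -> PlantPlan:
    return PlantPlan(n_full=2, rng_seed=7)
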