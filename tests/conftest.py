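import pytest

from ecckit.architecture import annotate_ecc
from ecckit.simulate import PanelSpec, gen_ecc_panel


@pytest.fixture(scope="session")
def canonical_panel():
    """Noise-free mixed panel (all five groups) with ground truth."""
    return gen_ecc_panel(PanelSpec(seed=11))


@pytest.fixture(scope="session")
def group_d_fixture():
    """One canonical group D record with its truth and annotation."""
    records, truths = gen_ecc_panel(
        PanelSpec(seed=7, counts={"A": 0, "B": 0, "C": 0, "D": 1, "E": 0})
    )
    record, truth = records[0], truths[0]
    return record, truth, annotate_ecc(record)


@pytest.fixture(scope="session")
def group_b_pair():
    """Two annotated group B records (the chimera test-bed)."""
    records, _ = gen_ecc_panel(
        PanelSpec(seed=13, counts={"A": 0, "B": 2, "C": 0, "D": 0, "E": 0})
    )
    return tuple(annotate_ecc(r) for r in records)
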