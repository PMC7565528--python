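import numpy as np
import pandas as pd
import pytest

from tmeomix import synthetic_data as sd
from tmeomix.io_formats import ExpressionTable
from tmeomix.preprocess import SampleDesign


@pytest.fixture(scope="session")
def study_ds():
    """The default study-like synthetic dataset (fixed seed)."""
    return sd.simulate(sd.study_config(7))


@pytest.fixture
def tiny_table():
    frame = pd.DataFrame(
        [[1.0, 4.0], [3.0, 2.0]], index=["g1", "g2"], columns=["s1", "s2"]
    )
    return ExpressionTable(frame, "mrna")


def make_design(groups: dict[str, int], tag: str = "s") -> SampleDesign:
    """A design with ``n`` samples per group label (e.g. {"EC": 4})."""
    design = SampleDesign()
    for group, n in groups.items():
        for i in range(1, n + 1):
            if group in ("TP", "TM"):
                design.add(f"{group}_{tag}{i}", "tumor", group)
            else:
                design.add(f"{group}_{tag}{i}", group[0], group[1])
    return design


def make_table(
    rng: np.random.Generator,
    molecules: list[str],
    design: SampleDesign,
    layer: str = "mrna",
    group_means: dict[tuple[str, str], float] | None = None,
    baseline: float = 8.0,
    sd: float = 0.1,
) -> ExpressionTable:
    """Gaussian table with optional per-(molecule, group) mean overrides."""
    cols = design.sample_ids
    data = np.full((len(molecules), len(cols)), baseline) + rng.normal(
        0, sd, (len(molecules), len(cols))
    )
    frame = pd.DataFrame(data, index=molecules, columns=cols)
    if group_means:
        for (mol, group), mean in group_means.items():
            samples = design.samples_in_group(group)
            frame.loc[mol, samples] += mean - baseline
    return ExpressionTable(frame, layer)
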