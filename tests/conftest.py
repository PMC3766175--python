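import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirqpcr import CtMatrix, PanelDef, SampleSheet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_ct(values: dict, samples: list, replicate: dict | None = None) -> CtMatrix:
    """Build a CtMatrix from {assay: [ct per sample]}; None = non-detected."""
    rows, assays, reps = [], [], []
    for assay, cts in values.items():
        rows.append([np.nan if c is None else float(c) for c in cts])
        assays.append(assay)
        reps.append((replicate or {}).get(assay, 1))
    idx = pd.MultiIndex.from_arrays([assays, reps], names=["assay", "replicate"])
    return CtMatrix(pd.DataFrame(rows, index=idx, columns=samples))


def random_ct(rng: np.random.Generator, n_assays=6, samples=("s1", "s2", "s3", "s4"),
              nd_prob=0.15) -> CtMatrix:
    vals = rng.uniform(18, 38, size=(n_assays, len(samples)))
    vals[rng.random(vals.shape) < nd_prob] = np.nan
    idx = pd.MultiIndex.from_arrays(
        [[f"a{i}" for i in range(n_assays)], np.ones(n_assays, dtype=int)],
        names=["assay", "replicate"],
    )
    return CtMatrix(pd.DataFrame(vals, index=idx, columns=list(samples)))


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    groups = {f"e{i}": "endometriosis" for i in range(1, 4)}
    groups.update({f"c{i}": "control" for i in range(1, 4)})
    return SampleSheet.from_groups(groups, calibrator="c1")


@pytest.fixture
def small_panel() -> PanelDef:
    return PanelDef(assays=["m1", "m2", "m3", "EC"], endogenous_controls=["EC"])
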