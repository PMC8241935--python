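import numpy as np
import pandas as pd
import pytest

import microtumor as mt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    return mt.PanelConfig(
        targets=["A", "B", "C"],
        isotype_controls=["IgG1"],
        isotype_map={"A": "IgG1", "B": "IgG1", "C": "IgG1"},
        ercc_controls=["ERCC1", "ERCC2"],
    )


def make_dataset(matrix: dict, areas, cd45, tissues=None, state="raw", controls=()):
    frame = pd.DataFrame(matrix)
    n = len(frame)
    frame.index = pd.Index([f"R{i+1}" for i in range(n)], name="roi_id")
    meta = pd.DataFrame(
        {
            "tissue_id": tissues if tissues is not None else ["T1"] * n,
            "mask_area": areas,
            "cd45_fraction": cd45,
        },
        index=frame.index,
    )
    return mt.ExpressionDataset(
        matrix=frame, roi_meta=meta, state=state, control_columns=list(controls)
    )


@pytest.fixture
def three_roi_raw(small_panel):
    return make_dataset(
        {
            "A": [10.0, 20.0, 30.0],
            "B": [5.0, 5.0, 5.0],
            "C": [1.0, 2.0, 3.0],
            "IgG1": [1.0, 1.0, 1.0],
            "ERCC1": [100.0, 100.0, 100.0],
            "ERCC2": [400.0, 400.0, 400.0],
        },
        areas=[1000.0, 2000.0, 1000.0],
        cd45=[0.371, 0.504, 0.017],
        controls=["IgG1", "ERCC1", "ERCC2"],
    )


@pytest.fixture(scope="session")
def processed_cohort():
    """Default synthetic cohort processed to density with compartments."""
    ds, truth = mt.gen_roi_counts(seed=7)
    panel = mt.default_panel(mt.RoiSimConfig())
    dens = mt.process_counts(ds, panel)
    cls = mt.classify_rois(dens)
    return dens.with_compartments(cls.labels), truth


@pytest.fixture(scope="session")
def fast_cfg():
    return mt.RunConfig(n_perm=1000, seed=0)
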