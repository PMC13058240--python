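import numpy as np
import pandas as pd
import pytest

from dyetrack import EventTable, SampleMeta, paperlike_config


@pytest.fixture
def mono_meta():
    return SampleMeta(
        sample_id="mono_X_stained_t0",
        culture_kind="monoculture_stained",
        competitor_a="X",
        stained_competitor="X",
        time_h=0.0,
    )


@pytest.fixture
def coc_meta():
    return SampleMeta(
        sample_id="co_r0.5_sX_p0_rep1_t0",
        culture_kind="coculture",
        competitor_a="X",
        competitor_b="Y",
        stained_competitor="X",
        initial_ratio=0.5,
        replicate=1,
        time_h=0.0,
    )


@pytest.fixture
def small_config():
    """Paper-like design at reduced event count for fast structural tests."""
    return paperlike_config(seed=7, n_events_per_sample=300, n_replicates=2)


def make_events(meta, dye, auto=None, area=None, labels=None):
    data = {"intensity_dye": np.asarray(dye, float)}
    if auto is not None:
        data["intensity_auto"] = np.asarray(auto, float)
    if area is not None:
        data["area"] = np.asarray(area, float)
    if labels is not None:
        data["true_label"] = labels
    return EventTable(meta=meta, events=pd.DataFrame(data))
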