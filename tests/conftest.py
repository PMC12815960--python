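import dataclasses
import logging

import pytest

from ppmr import dapstom_io, glmm_pipeline, synthetic_data

logging.getLogger("ppmr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """A small interaction-preset dataset shared by matching/fit tests."""
    cfg = dataclasses.replace(
        synthetic_data.preset("paper_interaction"), n_stomachs=500, seed=11
    )
    return synthetic_data.generate(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    ds = small_dataset
    matched = dapstom_io.build_matched_table(
        ds.stomachs, dapstom_io.EnvLayer(ds.sst), dapstom_io.EffortTable(ds.effort)
    )
    return glmm_pipeline.build_analysis_table(matched)
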