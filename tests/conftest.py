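import logging

import numpy as np
import pandas as pd
import pytest

from hormnet import pipeline, synthio

logging.getLogger("hormnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg() -> synthio.SimConfig:
    return synthio.SimConfig(n_varieties=1, n_genes=30, n_pathway_genes=12,
                             deg_fraction=0.4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg) -> synthio.Dataset:
    return synthio.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def fig4_run():
    """The deterministic hub fixture pushed through the full pipeline."""
    expr, horm, pathways, homologs = synthio.fig4_fixture()
    sheet = synthio.fixture_design()
    result = pipeline.run_pipeline(expr, horm, pathways, sheet)
    return {"expr": expr, "hormones": horm, "pathways": pathways,
            "homologs": homologs, "sheet": sheet, "result": result}


def make_sheet(n_days=2, n_reps=3, varieties=("V1",)) -> "pd.DataFrame":
    """Tiny hand-rolled sample sheet (day 0 + n_days treated days)."""
    from hormnet.io import SampleSheet
    rows = []
    days = [0] + [2 * (i + 1) for i in range(n_days)]
    for v in varieties:
        for rep in range(1, n_reps + 1):
            rows.append(dict(sample_id=f"{v}-0d-r{rep}", variety=v,
                             condition="control", day=0, replicate=rep))
        for cond, tag in (("control", "C"), ("drought", "D")):
            for day in days[1:]:
                for rep in range(1, n_reps + 1):
                    rows.append(dict(sample_id=f"{v}-{tag}{day}d-r{rep}",
                                     variety=v, condition=cond, day=day,
                                     replicate=rep))
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture()
def tiny_sheet():
    return make_sheet()
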