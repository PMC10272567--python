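import logging

import numpy as np
import pandas as pd
import pytest

from osmonet import io, pipeline, synthetic

logging.getLogger("osmonet").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic dataset shared across the session."""
    cfg = synthetic.SimConfig(seed=1)
    matrix, design, probe_map, tf, truth = synthetic.generate(cfg)
    return {
        "cfg": cfg,
        "matrix": matrix,
        "design": design,
        "probe_map": probe_map,
        "tf": tf,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def pipeline_bundle(default_sim):
    """Full default pipeline run on the shared synthetic dataset."""
    probe_map = io.filter_identity(default_sim["probe_map"])
    return pipeline.run_all(
        default_sim["matrix"],
        default_sim["design"],
        probe_map,
        default_sim["tf"],
        pipeline.PipelineConfig(seed=1),
    )


@pytest.fixture
def tiny_design():
    rows = []
    for organ in ("leaf", "root"):
        for genotype in ("M82", "Tondo"):
            for treatment in ("control", "peg"):
                for rep in (1, 2, 3):
                    rows.append(
                        {
                            "sample_id": f"{organ}_{genotype}_{treatment}_{rep}",
                            "genotype": genotype,
                            "organ": organ,
                            "treatment": treatment,
                            "replicate": rep,
                        }
                    )
    return io.SampleDesign(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
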