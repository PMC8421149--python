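import json
import os

import pytest

from smorfer.pipeline import RunConfig, run_pipeline
from smorfer.simulate import FixtureSpec, write_fixture

PINNED_SEED = 1


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=PINNED_SEED)


@pytest.fixture(scope="session")
def fixture_dir(fixture_spec, tmp_path_factory):
    """Synthetic genome + annotation + Ribo/TIS alignments on disk."""
    d = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(fixture_spec, d)
    return paths


@pytest.fixture(scope="session")
def fixture_truth(fixture_dir):
    with open(fixture_dir["truth"]) as fh:
        t = json.load(fh)
    t["planted_keys"] = {(p["seq_id"], p["strand"], p["start"], p["end"])
                         for p in t["planted"]}
    t["control_keys"] = {(p["seq_id"], p["strand"], p["start"], p["end"])
                         for p in t["controls"]}
    return t


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir, tmp_path_factory):
    """One full pipeline run shared across tests (deterministic inputs)."""
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = RunConfig(
        genome=fixture_dir["genome"],
        annotation=fixture_dir["annotation"],
        ribo_alignments=[fixture_dir["ribo"]],
        tis_alignments=[fixture_dir["tis"]],
        out_dir=str(out),
    )
    report, orfs = run_pipeline(cfg)
    return {"report": report, "orfs": orfs, "out_dir": str(out), "config": cfg}
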