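"""Shared fixtures: one synthetic study and one full pipeline run per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from trunkvoc import pipeline, synthetic

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_run_config(paths, out_dir, seed=0, **overrides) -> pipeline.RunConfig:
    return pipeline.RunConfig(
        design=str(paths["design"]),
        peaks=str(paths["peaks"]),
        alkanes=str(paths["alkanes"]),
        library=str(paths["library"]),
        calibration=str(paths["calibration"]),
        surrogates=str(paths["surrogates"]),
        out_dir=str(out_dir),
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """Default synthetic study (seed 0) written to disk once per session."""
    d = tmp_path_factory.mktemp("study")
    cfg = synthetic.default_config(seed=0)
    paths = synthetic.write_study(cfg, d)
    return {"config": cfg, "paths": paths, "dir": d}


@pytest.fixture(scope="session")
def run_bundle(study_dir, tmp_path_factory):
    """Full pipeline bundle over the default study, computed once."""
    out = tmp_path_factory.mktemp("run")
    cfg = make_run_config(study_dir["paths"], out, seed=0)
    bundle = pipeline.run_pipeline(cfg, write=True)
    return {"bundle": bundle, "cfg": cfg, "out": out, "study": study_dir}
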