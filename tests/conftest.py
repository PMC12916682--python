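"""Shared fixtures: small synthetic datasets and one full study-scale run."""

from __future__ import annotations

import warnings
from pathlib import Path

import pytest

from faerspv import pipeline, synthetic


@pytest.fixture(scope="session")
def small_sim():
    """A quick ~2,100-case synthetic dataset with its truth table."""
    cfg = synthetic.default_config(seed=7, scale=0.05)
    files, truth = synthetic.generate_dataset(cfg)
    return cfg, files, truth


def run_study(tmp_dir: Path, seed: int, scale: float = 1.0):
    """Generate a dataset and run the full pipeline on it."""
    sim_dir = tmp_dir / "sim"
    out_dir = tmp_dir / "out"
    cfg = synthetic.default_config(seed=seed, scale=scale)
    _, truth = synthetic.generate_dataset(cfg, out_dir=sim_dir)
    (sim_dir / "direct.txt").write_text(
        "\n".join(synthetic.DEFAULT_DIRECT_WATCHLIST) + "\n", encoding="utf-8"
    )
    (sim_dir / "indirect.txt").write_text(
        "\n".join(synthetic.DEFAULT_INDIRECT_WATCHLIST) + "\n", encoding="utf-8"
    )
    rc = pipeline.RunConfig(
        input_dir=str(sim_dir),
        output_dir=str(out_dir),
        drug_dictionary=str(sim_dir / "drug_dictionary.tsv"),
        targets=[synthetic.DENOSUMAB, synthetic.ROMOSOZUMAB],
        hierarchy=str(sim_dir / "hierarchy.tsv"),
        direct_watchlist=str(sim_dir / "direct.txt"),
        indirect_watchlist=str(sim_dir / "indirect.txt"),
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = pipeline.run_pipeline(rc)
    return cfg, truth, rc, manifest


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full-scale (~50,000 cases) generate → pipeline run, shared
    across the acceptance tests."""
    tmp = tmp_path_factory.mktemp("study")
    cfg, truth, rc, manifest = run_study(tmp, seed=1)
    return {"tmp": tmp, "config": cfg, "truth": truth, "run_config": rc,
            "manifest": manifest, "out": Path(rc.output_dir)}
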