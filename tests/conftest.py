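import pytest
from hypothesis import HealthCheck, settings

from matsip import pipeline as pl
from matsip import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_like_experiment(tmp_path_factory):
    """The packaged default scenario, generated once per session."""
    out = tmp_path_factory.mktemp("scenario")
    data = sim.generate_experiment(sim.paper_like_config(seed=0), out)
    data["dir"] = out
    return data


@pytest.fixture(scope="session")
def paper_like_run(paper_like_experiment, tmp_path_factory):
    """Full pipeline results on the packaged scenario."""
    out = tmp_path_factory.mktemp("results")
    src = paper_like_experiment["dir"]
    cfg = {
        "inputs": {
            "irms": str(src / "irms_bulk.tsv"),
            "gcms": str(src / "gcms_injections.tsv"),
            "proteins": str(src / "proteins.tsv"),
            "patterns": str(src / "peptide_patterns.tsv"),
        },
        "out_dir": str(out),
    }
    return pl.run(cfg)
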