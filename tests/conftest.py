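import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def sim_dir(tmp_path):
    """A small complete fixture set written by the simulate subcommand."""
    from click.testing import CliRunner

    from asmeval.cli import main

    out = tmp_path / "fixtures"
    res = CliRunner().invoke(
        main,
        ["simulate", "--seed", "7", "--n-transcripts", "30",
         "--outdir", str(out)],
        catch_exceptions=False,
    )
    assert res.exit_code == 0
    return out
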