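import pytest

from hap_panel import transcripts as tx
from hap_panel.panel import default_panel
from hap_panel.pipeline import run_fixture_pipeline


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def reference():
    return tx.reference_sequence()


@pytest.fixture(scope="session")
def models():
    return tx.transcript_models()


@pytest.fixture(scope="session")
def fixture_run():
    """Full pipeline over the bundled worked-example tables."""
    fixture, candidates, traces, findings, summary = run_fixture_pipeline()
    return {
        "fixture": fixture,
        "candidates": candidates,
        "traces": traces,
        "findings": findings,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small generated cohort shared across tests (n=60, fixed seed)."""
    from hap_panel.simulate import SimulationConfig, generate

    outdir = tmp_path_factory.mktemp("sim60")
    cfg = SimulationConfig(n_samples=60, seed=11, digenic_pairs=3,
                           biallelic_cases=2)
    return cfg, generate(cfg, outdir)
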