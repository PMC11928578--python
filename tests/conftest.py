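import numpy as np
import pytest

from ervclock.simulate import SimulationConfig, simulate_insertions


@pytest.fixture(scope="session")
def small_sim():
    """A small planted genome shared by mining/annotation tests."""
    cfg = SimulationConfig(
        rng_seed=11, host_length=600_000, min_spacing=25_000,
        n_per_subgroup={"A": 4, "B1": 4, "B2": 4, "C": 2})
    return simulate_insertions(cfg)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full-pipeline run on a 50-provirus genome, with its ground truth.

    Session-scoped: this is the expensive fixture behind the
    planted-feature recovery checks.
    """
    from ervclock.pipeline import PipelineConfig, run_pipeline
    out = tmp_path_factory.mktemp("recovery")
    cfg = PipelineConfig(
        out_dir=str(out),
        simulation=SimulationConfig(
            rng_seed=1, host_length=2_000_000, min_spacing=25_000,
            n_per_subgroup={"A": 13, "B1": 20, "B2": 14, "C": 3}))
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def match_calls_to_truth(result):
    """Pair each ProvirusCall with its TruthRecord by genome position."""
    pairs = []
    for call in result.calls:
        start = call.locus_start + call.provirus[0]
        truth = min(result.truth, key=lambda t: abs(t.start - start))
        pairs.append((call, truth))
    return pairs
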