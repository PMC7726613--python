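import os

import pytest

import ampliscreen as am
from ampliscreen import simulate as sim
from ampliscreen.panel import default_panel

# Desk-scale depth means: comfortably above every per-sample floor while
# keeping simulated runs small.
DESK_DEPTHS = {
    "bacteria_16s": 6000,
    "s200x6": 1500,
    "cox1": 1200,
    "kdr": 1500,
    "mammal_16s": 2500,
    "parasite_virus": 1500,
}


def noise_free_run(tmp_path, n_samples=24, n_controls=4, seed=1):
    """Simulate, emit and fully process one error-free run."""
    truth = sim.simulate_cohort(
        n_samples, n_sites=3, site_effect_size=0.2, n_controls=n_controls, seed=seed
    )
    panel = default_panel(truth.sample_ids, seed=seed)
    config = sim.RunConfig(depth_means=dict(DESK_DEPTHS), depth_shape=200.0, seed=seed)
    paths = sim.emit_run(truth, panel, config, str(tmp_path))
    pc = am.PipelineConfig(
        fastq1=paths["r1"],
        fastq2=paths["r2"],
        output_dir=str(tmp_path / "out"),
        metadata_path=paths["samples"],
        n_perm=99,
    )
    result = am.run_pipeline(pc, panel, control_ids=[c.sample_id for c in truth.controls()])
    return truth, panel, config, paths, result


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A 24-mosquito noise-free run, processed once and shared."""
    tmp = tmp_path_factory.mktemp("run")
    return noise_free_run(tmp)


@pytest.fixture()
def panel12():
    return default_panel([f"S{i:02d}" for i in range(12)], seed=7)
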