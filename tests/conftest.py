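import pytest

from mcpgchip.pipeline import config_from_manifest, run_pipeline
from mcpgchip.simulate import SimulationParams, generate_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One full synthetic study at default conditions, written to disk."""
    outdir = tmp_path_factory.mktemp("dataset")
    dataset = generate_dataset(11)
    manifest = dataset.write(outdir)
    return dataset, manifest


@pytest.fixture(scope="session")
def pipeline_report(default_dataset, tmp_path_factory):
    """Full pipeline run on the default synthetic study."""
    _, manifest = default_dataset
    out = tmp_path_factory.mktemp("pipeline_out")
    config = config_from_manifest(manifest, str(out), seed=11)
    report = run_pipeline(config)
    return report, out


@pytest.fixture()
def small_params():
    """Scaled-down study for tests that regenerate data repeatedly."""
    return SimulationParams(
        n_chroms=2,
        chrom_length=150_000,
        n_wt_specific=40,
        n_shared=40,
        n_mut_specific=10,
        n_targets=8,
        n_decoy_up_genes=4,
        n_up_both_genes=2,
        n_expression_genes=400,
    )
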