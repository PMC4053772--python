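import pytest

from prc1map.pipeline import RunConfig, run
from prc1map.simulate import GeneratorConfig, generate

#: Seed for every randomized fixture in the suite.
SUITE_SEED = 11


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact labelled landscape: 300 genes, 120 planted targets."""
    config = GeneratorConfig(n_genes=300, n_targets=120)
    dataset = generate(config, seed=SUITE_SEED)
    outdir = tmp_path_factory.mktemp("small_fixture")
    dataset.write(outdir)
    return dataset, outdir


@pytest.fixture(scope="session")
def small_report(small_dataset):
    """Full pipeline run over the small landscape, senescence pair included."""
    dataset, outdir = small_dataset
    report = run(
        RunConfig(
            manifest=str(outdir / "manifest.yaml"),
            genes=str(outdir / "genes.gtf"),
            counts=str(outdir / "counts.tsv"),
            outdir=str(outdir / "out"),
            concordance_pair=("Hs68", "Hs68_senescent"),
        )
    )
    return dataset, outdir, report


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Study-scale run: 1,000 planted targets over 2,500 genes (defaults)."""
    config = GeneratorConfig()
    dataset = generate(config, seed=SUITE_SEED)
    outdir = tmp_path_factory.mktemp("study_fixture")
    dataset.write(outdir)
    report = run(
        RunConfig(
            manifest=str(outdir / "manifest.yaml"),
            genes=str(outdir / "genes.gtf"),
            counts=str(outdir / "counts.tsv"),
            outdir=str(outdir / "out"),
            concordance_pair=("Hs68", "Hs68_senescent"),
        )
    )
    return dataset, outdir, report
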