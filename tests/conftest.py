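import numpy as np
import pytest

from autozygmap.synthetic import SimulationConfig, build_gene_fixture, simulate_study

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across the suite."""
    return simulate_study(SimulationConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def gene_fixture():
    """The default 876-codon, 19-exon gene with the planted frameshift geometry."""
    return build_gene_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Synthetic study written to disk in all on-disk formats."""
    from click.testing import CliRunner

    from autozygmap.cli import main

    out = tmp_path_factory.mktemp("simdata")
    result = CliRunner().invoke(
        main, ["simulate", "--seed", str(STUDY_SEED), "--out-dir", str(out)]
    )
    assert result.exit_code == 0, result.output
    return out


@pytest.fixture(scope="session")
def pipeline_summary(sim_dir, tmp_path_factory):
    from autozygmap.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("results")
    config = PipelineConfig(
        ped=str(sim_dir / "genotypes.ped"),
        map=str(sim_dir / "markers.map"),
        roster=str(sim_dir / "roster.tsv"),
        vcf=str(sim_dir / "variants.vcf"),
        gff3=str(sim_dir / "genes.gff3"),
        fasta=str(sim_dir / "reference.fa"),
        out_dir=str(out),
    )
    return run_pipeline(config)
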