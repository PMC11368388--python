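from types import SimpleNamespace

import pytest

from synteny_conserve import pipeline
from synteny_conserve.fixtures import FixtureSpec, SharedBlock, generate_genome_set


@pytest.fixture(scope="session")
def run_env(tmp_path_factory):
    """A generated 5-genome set run through validate + builtin blastn.

    Genomes SYNG00..SYNG04: 3 core genes everywhere, a 2-gene block
    shared by (0,1) at 80% identity, a 1-gene block shared by (1,2,3)
    at 90%, and one planted unique gene per genome.  Session-scoped;
    tests must not mutate the frames.
    """
    d = tmp_path_factory.mktemp("run_env")
    spec = FixtureSpec(
        n_genomes=5,
        n_core=3,
        shared_blocks=[
            SharedBlock(n_genes=2, genomes=(0, 1), identity=80.0),
            SharedBlock(n_genes=1, genomes=(1, 2, 3), identity=90.0),
        ],
        n_unique_per_genome=1,
        seed=11,
    )
    manifest = generate_genome_set(spec, d / "genbank")
    val = pipeline.validate_job(d)
    blast = pipeline.blast_job(d, mode="blastn", engine="builtin")
    return SimpleNamespace(
        dir=d,
        spec=spec,
        manifest=manifest,
        records=val["records"],
        reports=val["reports"],
        feature_table=val["feature_table"],
        processed=val["processed"],
        summary=blast["summary"],
        uniqueness=blast["uniqueness"],
    )


@pytest.fixture()
def selection_csv(run_env, tmp_path):
    path = tmp_path / "selection.csv"
    path.write_text(
        "sequence,orientation\nSYNG00,1\nSYNG01,1\nSYNG02,0\nSYNG03,1\n"
    )
    return path
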