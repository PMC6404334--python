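import pandas as pd
import pytest

from gsepd.io import write_counts, write_gene_sets, write_sample_table
from gsepd.model import Config, Contrast, CountMatrix, SampleTable
from gsepd.simulate import golden_spec, simulate_study


@pytest.fixture(scope="session")
def golden_study():
    """The bundled end-to-end study: one 10-gene term with log2 effect 4,
    6 tested samples per group, 4 non-tested interpolating samples."""
    return simulate_study(golden_spec())


@pytest.fixture
def golden_files(tmp_path, golden_study):
    cm, st, coll, _ = golden_study
    paths = {
        "counts": tmp_path / "counts.tsv",
        "samples": tmp_path / "samples.tsv",
        "gene_sets": tmp_path / "gene_sets.tsv",
        "term_names": tmp_path / "term_names.tsv",
    }
    write_counts(cm, paths["counts"])
    write_sample_table(st, paths["samples"])
    write_gene_sets(coll, paths["gene_sets"], paths["term_names"])
    return paths


@pytest.fixture
def tiny_counts():
    return CountMatrix(
        pd.DataFrame(
            {"s1": [4, 10, 100], "s2": [8, 20, 200], "s3": [4, 10, 100]},
            index=["g1", "g2", "g3"],
        )
    )


@pytest.fixture
def four_sample_table():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "condition": ["A", "A", "B", "B"],
                "short_label": ["a1", "a2", "b1", "b2"],
            }
        )
    )


@pytest.fixture
def ab_contrast():
    return Contrast("A", "B")


@pytest.fixture
def default_config():
    return Config()
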