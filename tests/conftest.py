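import numpy as np
import pandas as pd
import pytest

from pseudomix import AnnotatedCorpus, SyntheticCorpusConfig, TypeNode, generate_corpus
from pseudomix.preprocess import cp10k_normalize, filter_rare_celltypes


def make_corpus(blocks, n_genes=6, value=1.0, seed=0):
    """Hand-built corpus: blocks of (patient, subtype, major, minor, subset, n_cells).

    Expression is positive pseudo-random so cells are distinct; exact values
    are irrelevant to the membership/labelling operations under test.
    """
    rng = np.random.default_rng(seed)
    rows, records = [], []
    for patient, subtype, major, minor, subset, n in blocks:
        for k in range(n):
            rows.append(value + rng.random(n_genes))
            records.append(
                dict(
                    cell_id=f"{patient}|{subset}|{k}",
                    patient=patient,
                    subtype=subtype,
                    major=major,
                    minor=minor,
                    subset=subset,
                    is_synthesized=False,
                )
            )
    table = pd.DataFrame.from_records(records).set_index("cell_id")
    genes = [f"g{i}" for i in range(n_genes)]
    return AnnotatedCorpus.from_arrays(np.vstack(rows), genes, table)


@pytest.fixture(scope="session")
def small_config():
    """A compact generated-corpus config: 3 patients, 4 majors, 240 genes.

    Includes an absent type (B absent in p2) and a rare type (8 cells of D in
    p3, below the 10-cell filter).
    """
    hierarchy = [
        TypeNode("cancer_epithelial", "cancer_basal", "cancer_basal"),
        TypeNode("cancer_epithelial", "cancer_luminal", "cancer_luminal"),
        TypeNode("t_cells", "cd4_t", "cd4_t"),
        TypeNode("t_cells", "cd8_t", "cd8_t"),
        TypeNode("myeloid", "macrophage", "macrophage"),
        TypeNode("normal_epithelial", "mature_luminal", "mature_luminal"),
    ]
    abundance = {
        ("p1", "cancer_basal"): 180, ("p1", "cancer_luminal"): 60,
        ("p1", "cd4_t"): 120, ("p1", "cd8_t"): 100,
        ("p1", "macrophage"): 150, ("p1", "mature_luminal"): 40,
        ("p2", "cancer_basal"): 200, ("p2", "cancer_luminal"): 0,
        ("p2", "cd4_t"): 110, ("p2", "cd8_t"): 130,
        ("p2", "macrophage"): 90, ("p2", "mature_luminal"): 55,
        ("p3", "cancer_basal"): 160, ("p3", "cancer_luminal"): 70,
        ("p3", "cd4_t"): 140, ("p3", "cd8_t"): 105,
        ("p3", "macrophage"): 8, ("p3", "mature_luminal"): 65,
    }
    return SyntheticCorpusConfig(
        patient_subtype={"p1": "ER+", "p2": "HER2+", "p3": "TNBC"},
        hierarchy=hierarchy,
        abundance=abundance,
        n_genes=240,
        markers_per_type=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def prepared_corpus(small_corpus):
    """Normalized + rare-filtered version of the small generated corpus."""
    norm = cp10k_normalize(small_corpus)
    filt, _ = filter_rare_celltypes(norm, level="major", min_cells=10)
    return filt
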