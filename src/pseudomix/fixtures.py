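"""Synthetic annotated scRNA-seq corpora for offline benchmarking.

The generator emulates the structural properties of the breast-tumour
single-cell atlases the benchmark was designed around: multiple patients of
three molecular subtypes (ER+, HER2+, TNBC), a three-level cell-type
hierarchy (major > minor > subset), per-patient abundances that range from a
handful of cells to over a thousand with some types entirely absent in some
patients, and disjoint marker-gene sets that make the types separable.

The count model is deliberately minimal: gene counts are negative binomial
with a per-type mean that is ``marker_fold`` times larger on that type's
marker genes, modulated by a per-patient log-normal factor.  This gives
type-separable signal plus donor heterogeneity, which is all the downstream
recovery tests need; it does not attempt splatter-style realism (batch
trajectories, doublets, ambient RNA are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .corpus import AnnotatedCorpus, LEVELS

SUBTYPES = ("ER+", "HER2+", "TNBC")


@dataclass(frozen=True)
class TypeNode:
    """One leaf of the cell-type hierarchy: (major, minor, subset) labels."""

    major: str
    minor: str
    subset: str


@dataclass
class SyntheticCorpusConfig:
    """Everything needed to generate one synthetic corpus.

    Parameters
    ----------
    patient_subtype
        Map patient id -> molecular subtype label (ER+/HER2+/TNBC).
    hierarchy
        The cell-type tree as a list of leaves; every (major, minor, subset)
        triple must nest consistently.
    abundance
        Map (patient, subset label) -> cell count.  Zero means the type is
        absent in that patient; every leaf must have >0 cells in at least one
        patient.
    n_genes, markers_per_type
        Gene-space size and number of disjoint marker genes per leaf type.
    baseline_mean, marker_fold, dispersion
        Negative-binomial parameters: baseline per-gene mean, multiplicative
        up-weighting of a type's markers, and the NB size/dispersion
        parameter (smaller = more overdispersed).
    patient_effect_sd
        Standard deviation (log scale) of the per-patient, per-gene
        log-normal multiplicative effect.  Zero disables donor heterogeneity.
    """

    patient_subtype: Mapping[str, str]
    hierarchy: list[TypeNode]
    abundance: Mapping[tuple[str, str], int]
    n_genes: int = 2000
    markers_per_type: int = 20
    baseline_mean: float = 0.5
    marker_fold: float = 8.0
    dispersion: float = 2.0
    patient_effect_sd: float = 0.15
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return len(self.patient_subtype)

    @property
    def leaves(self) -> list[str]:
        return [node.subset for node in self.hierarchy]

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.n_genes < 1 or self.markers_per_type < 1:
            raise ValueError("n_genes and markers_per_type must be positive")
        if min(self.baseline_mean, self.marker_fold, self.dispersion) <= 0:
            raise ValueError("baseline_mean, marker_fold and dispersion must be positive")
        if self.patient_effect_sd < 0:
            raise ValueError("patient_effect_sd must be non-negative")
        leaves = self.leaves
        if len(set(leaves)) != len(leaves):
            raise ValueError("subset labels must be unique across the hierarchy")
        if self.n_genes < self.markers_per_type * len(leaves):
            raise ValueError(
                "not enough genes for disjoint marker sets: need at least "
                f"{self.markers_per_type * len(leaves)}"
            )
        for (patient, leaf), n in self.abundance.items():
            if patient not in self.patient_subtype:
                raise ValueError(f"abundance refers to unknown patient {patient!r}")
            if leaf not in leaves:
                raise ValueError(f"abundance refers to unknown type {leaf!r}")
            if n < 0:
                raise ValueError("abundance counts must be non-negative")
        totals = {leaf: 0 for leaf in leaves}
        for (_, leaf), n in self.abundance.items():
            totals[leaf] += n
        orphans = [leaf for leaf, n in totals.items() if n == 0]
        if orphans:
            raise ValueError(f"types with no cells in any patient: {orphans}")
        if sum(self.abundance.values()) == 0:
            raise ValueError("corpus would contain zero cells")


def marker_table(config: SyntheticCorpusConfig) -> pd.DataFrame:
    """Deterministic disjoint marker-gene assignment, one block per leaf type.

    Markers occupy the first ``markers_per_type * n_leaves`` genes in
    hierarchy order, so the assignment depends only on the config, not on the
    RNG state.
    """
    rows = []
    for i, node in enumerate(config.hierarchy):
        start = i * config.markers_per_type
        for j in range(config.markers_per_type):
            rows.append({"type": node.subset, "gene": f"g{start + j:05d}"})
    return pd.DataFrame(rows)


def generate_corpus(config: SyntheticCorpusConfig) -> AnnotatedCorpus:
    """Draw a corpus from the negative-binomial model; reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    leaves = {node.subset: node for node in config.hierarchy}

    # per-type mean vectors: baseline everywhere, marker_fold on own markers
    type_means = {}
    for i, node in enumerate(config.hierarchy):
        mu = np.full(config.n_genes, config.baseline_mean)
        start = i * config.markers_per_type
        mu[start : start + config.markers_per_type] *= config.marker_fold
        type_means[node.subset] = mu

    patient_factors = {
        p: np.exp(rng.normal(0.0, config.patient_effect_sd, size=config.n_genes))
        if config.patient_effect_sd > 0
        else np.ones(config.n_genes)
        for p in config.patient_subtype
    }

    blocks: list[np.ndarray] = []
    records: list[dict] = []
    theta = config.dispersion
    for patient in config.patient_subtype:
        for node in config.hierarchy:
            n = int(config.abundance.get((patient, node.subset), 0))
            if n == 0:
                continue
            mu = type_means[node.subset] * patient_factors[patient]
            p_nb = theta / (theta + mu)
            counts = rng.negative_binomial(theta, p_nb, size=(n, config.n_genes))
            blocks.append(counts.astype(np.float64))
            for k in range(n):
                records.append(
                    {
                        "cell_id": f"{patient}|{node.subset}|{k}",
                        "patient": patient,
                        "subtype": config.patient_subtype[patient],
                        "major": node.major,
                        "minor": node.minor,
                        "subset": node.subset,
                        "is_synthesized": False,
                    }
                )
    X = np.vstack(blocks)
    cell_table = pd.DataFrame.from_records(records).set_index("cell_id")
    corpus = AnnotatedCorpus.from_arrays(X, genes, cell_table)
    corpus.adata.uns["markers"] = marker_table(config)
    return corpus


# ---------------------------------------------------------------------------
# Demo configuration: a breast-tumour-atlas-shaped corpus at desk scale.
# ---------------------------------------------------------------------------

_DEMO_HIERARCHY: list[TypeNode] = [
    TypeNode("cancer_epithelial", "cancer_basal", "cancer_basal"),
    TypeNode("cancer_epithelial", "cancer_luminal", "cancer_luminal"),
    TypeNode("normal_epithelial", "luminal_progenitors", "luminal_progenitors"),
    TypeNode("normal_epithelial", "mature_luminal", "mature_luminal"),
    TypeNode("normal_epithelial", "myoepithelial", "myoepithelial"),
    TypeNode("t_cells", "cd4_t", "cd4_naive"),
    TypeNode("t_cells", "cd4_t", "cd4_treg"),
    TypeNode("t_cells", "cd8_t", "cd8_cytotoxic"),
    TypeNode("t_cells", "cd8_t", "cd8_exhausted"),
    TypeNode("t_cells", "nk_cells", "nk_cells"),
    TypeNode("b_cells", "b_naive", "b_naive"),
    TypeNode("b_cells", "b_memory", "b_memory"),
    TypeNode("myeloid", "macrophage", "macro_m1"),
    TypeNode("myeloid", "macrophage", "macro_m2"),
    TypeNode("myeloid", "dc", "dc"),
    TypeNode("myeloid", "monocyte", "monocyte"),
    TypeNode("endothelial", "endo_vascular", "endo_vascular"),
    TypeNode("endothelial", "endo_lymphatic", "endo_lymphatic"),
    TypeNode("CAFs", "myCAF", "myCAF"),
    TypeNode("CAFs", "iCAF", "iCAF"),
    TypeNode("PVL", "pvl_immature", "pvl_immature"),
    TypeNode("PVL", "pvl_differentiated", "pvl_differentiated"),
    TypeNode("plasmablasts", "plasmablast_igg", "plasmablast_igg"),
    TypeNode("plasmablasts", "plasmablast_iga", "plasmablast_iga"),
]

MAJOR_TYPES = tuple(dict.fromkeys(n.major for n in _DEMO_HIERARCHY))


def demo_config(seed: int = 0, **overrides) -> SyntheticCorpusConfig:
    """The default demo corpus: 6 patients (2 per subtype), 9 major types
    with 2-3 minor children each, 2000 genes, per-type abundances from 0 to
    1500 cells.

    The cancer-epithelial leaves dominate each patient (mimicking tumour
    content); other types span rare (<10 cells, exercising the rare-type
    filter) to moderate, and roughly one in eight (patient, type) pairs is
    absent outright.  Abundances are drawn deterministically from ``seed``.
    """
    patients = {
        "P1": "ER+",
        "P2": "ER+",
        "P3": "HER2+",
        "P4": "HER2+",
        "P5": "TNBC",
        "P6": "TNBC",
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1]))
    abundance: dict[tuple[str, str], int] = {}
    leaves = [n.subset for n in _DEMO_HIERARCHY]
    cancer_leaves = {n.subset for n in _DEMO_HIERARCHY if n.major == "cancer_epithelial"}
    for pi, patient in enumerate(patients):
        for leaf in leaves:
            if pi == 0 and leaf == "cancer_basal":
                n = 1500  # one patient carries the extreme of the abundance range
            elif leaf in cancer_leaves:
                n = int(rng.integers(250, 701))
            elif rng.uniform() < 0.12:
                n = 0  # absent type for this patient
            elif rng.uniform() < 0.15:
                n = int(rng.integers(3, 10))  # rare: removed by the <10 filter
            else:
                n = int(np.round(np.exp(rng.uniform(np.log(15), np.log(300)))))
            abundance[(patient, leaf)] = n
    # guarantee every leaf exists somewhere
    for leaf in leaves:
        if all(abundance[(p, leaf)] == 0 for p in patients):
            abundance[(next(iter(patients)), leaf)] = 50
    cfg = SyntheticCorpusConfig(
        patient_subtype=patients,
        hierarchy=list(_DEMO_HIERARCHY),
        abundance=abundance,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg
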