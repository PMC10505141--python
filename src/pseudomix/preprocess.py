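"""Normalization, rare-type filtering, patient splitting and gene alignment.

The pipeline order mirrors the benchmark's: counts-per-10,000 normalization
(no log transform) comes first, then per-patient removal of cell types with
fewer than 10 cells, then the patient-level train/test split with
representation checks, with gene intersection / label collapsing reserved
for cross-corpus runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus import DROP, LEVELS, AnnotatedCorpus, CorpusError

CP10K_TOTAL = 10_000.0


@dataclass(frozen=True)
class SplitPlan:
    """A patient-level train/test assignment.

    Train and test sets must be disjoint and non-empty; by default
    :func:`split_by_patient` additionally verifies that every major cell type
    and every molecular subtype present in the corpus appears on both sides,
    so that no test condition is unseen at training time.
    """

    train_patients: frozenset[str]
    test_patients: frozenset[str]

    def __init__(self, train_patients, test_patients):
        object.__setattr__(self, "train_patients", frozenset(train_patients))
        object.__setattr__(self, "test_patients", frozenset(test_patients))
        if not self.train_patients or not self.test_patients:
            raise ValueError("train and test patient sets must both be non-empty")
        overlap = self.train_patients & self.test_patients
        if overlap:
            raise ValueError(f"patients assigned to both sides: {sorted(overlap)}")


def cp10k_normalize(corpus: AnnotatedCorpus) -> AnnotatedCorpus:
    """Scale each cell so its counts sum to 10,000 (no log transform).

    Idempotent: normalizing an already-normalized corpus is a no-op up to
    floating point.  Within-cell relative abundances are preserved exactly.
    """
    out = corpus.copy()
    X = out.adata.X
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        totals = np.asarray(X).sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        cell = out.adata.obs_names[zero[0]]
        raise CorpusError(f"cell {cell!r} has zero total counts and cannot be normalized")
    scale = CP10K_TOTAL / totals
    if sp.issparse(X):
        out.adata.X = sp.diags(scale) @ X
    else:
        out.adata.X = np.asarray(X) * scale[:, None]
    return out


def filter_rare_celltypes(
    corpus: AnnotatedCorpus, level: str = "major", min_cells: int = 10
) -> tuple[AnnotatedCorpus, pd.DataFrame]:
    """Drop, per patient, the cells of types with fewer than ``min_cells``
    cells in that patient at the given lineage level.

    A type with exactly ``min_cells`` cells is retained ("fewer than" is
    strict).  Returns the filtered corpus and a removal log with one row per
    removed (patient, type) group.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown lineage level {level!r}")
    obs = corpus.obs
    sizes = obs.groupby(["patient", level], observed=True).size()
    small = sizes[sizes < min_cells]
    log = (
        small.rename("n_removed")
        .reset_index()
        .rename(columns={level: "type"})
        .assign(level=level)
    )
    if small.empty:
        return corpus.copy(), log
    key = pd.MultiIndex.from_frame(obs[["patient", level]])
    keep = ~key.isin(small.index)
    return corpus.subset_cells(np.asarray(keep)), log


def split_by_patient(
    corpus: AnnotatedCorpus, plan: SplitPlan, *, override: bool = False
) -> tuple[AnnotatedCorpus, AnnotatedCorpus]:
    """Partition the cells by patient into train and test corpora.

    Unless ``override`` is set, raises if any major cell type or molecular
    subtype present in the corpus is missing from either side.
    """
    known = set(corpus.patients)
    unknown = (plan.train_patients | plan.test_patients) - known
    if unknown:
        raise CorpusError(f"plan references unknown patients: {sorted(unknown)}")
    if not override:
        _check_representation(corpus, plan)
    obs = corpus.obs
    train = corpus.subset_cells(obs["patient"].isin(plan.train_patients).to_numpy())
    test = corpus.subset_cells(obs["patient"].isin(plan.test_patients).to_numpy())
    return train, test


def _check_representation(corpus: AnnotatedCorpus, plan: SplitPlan) -> None:
    obs = corpus.obs
    problems: list[str] = []
    for side, patients in (("train", plan.train_patients), ("test", plan.test_patients)):
        mask = obs["patient"].isin(patients)
        majors_missing = set(obs["major"]) - set(obs.loc[mask, "major"])
        if majors_missing:
            problems.append(f"{side} side lacks major type(s) {sorted(majors_missing)}")
        if "subtype" in obs:
            sub_missing = set(obs["subtype"].dropna()) - set(obs.loc[mask, "subtype"].dropna())
            if sub_missing:
                problems.append(f"{side} side lacks molecular subtype(s) {sorted(sub_missing)}")
    if problems:
        raise CorpusError(
            "split fails representation checks (pass override=True to force): "
            + "; ".join(problems)
        )


def intersect_genes(corpora: list[AnnotatedCorpus]) -> list[AnnotatedCorpus]:
    """Restrict all corpora to their common genes, in lexicographic order.

    Expression values of retained genes are unchanged; the shared ordering
    makes downstream outputs bit-stable across runs.
    """
    if len(corpora) < 2:
        raise ValueError("need at least two corpora to intersect")
    common: set[str] = set(corpora[0].genes)
    for c in corpora[1:]:
        common &= set(c.genes)
    if not common:
        raise CorpusError("gene intersection is empty")
    order = sorted(common)
    return [c.subset_genes(order) for c in corpora]


def collapse_labels(
    corpus: AnnotatedCorpus, mapping: dict[str, str]
) -> AnnotatedCorpus:
    """Relabel cell types (e.g. DC/TAM -> myeloid for cross-corpus runs).

    Mapping keys may name labels at any lineage level; unmapped labels pass
    through.  Labels mapped to the reserved token :data:`~pseudomix.corpus.DROP`
    remove their cells entirely.  The label hierarchy is re-validated after
    relabeling.
    """
    labels_present: set[str] = set()
    for level in LEVELS:
        labels_present |= set(corpus.obs[level].astype(str))
    missing = set(mapping) - labels_present
    if missing:
        raise CorpusError(f"mapping keys not present in corpus: {sorted(missing)}")

    drop_labels = [k for k, v in mapping.items() if v == DROP]
    drop_mask = np.zeros(corpus.n_cells, dtype=bool)
    for level in LEVELS:
        drop_mask |= corpus.obs[level].astype(str).isin(drop_labels).to_numpy()
    keep = ~drop_mask
    if not keep.any():
        raise CorpusError("label collapsing removed every cell")
    out = corpus.subset_cells(keep)
    for level in LEVELS:
        col = out.adata.obs[level].astype(str)
        out.adata.obs[level] = col.map(lambda x: mapping.get(x, x))
    out.validate()
    return out
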