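"""Single-cell reference profiles and per-type signature matrices.

Reference-based deconvolution must be blind to the synthesized cells used
for mixture simulation, so the reference retains original cells only
(``is_synthesized == False``) from the training patients.  The signature
matrix is the per-type mean CP10K profile, optionally restricted to each
type's top marker genes ranked by fold-change against the mean of the other
types.  Construction is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import AnnotatedCorpus, CorpusError, resolve_labels


@dataclass
class ReferenceProfile:
    """Original-cells-only expression with working-level type labels."""

    expression: pd.DataFrame  # cells x genes (CP10K)
    labels: pd.Series  # per-cell type at the experiment's lineage level
    patients: pd.Series

    @property
    def types(self) -> list[str]:
        return sorted(self.labels.unique())

    def require_types(self, needed: Sequence[str]) -> None:
        missing = set(needed) - set(self.types)
        if missing:
            raise CorpusError(
                f"reference lacks original cells for type(s): {sorted(missing)}"
            )


@dataclass
class SignatureMatrix:
    """Genes x types matrix of per-type mean expression."""

    data: pd.DataFrame  # genes x types

    @property
    def types(self) -> list[str]:
        return list(self.data.columns)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


def build_reference(
    corpus: AnnotatedCorpus,
    level: str | Mapping[str, str] = "major",
    required_types: Sequence[str] | None = None,
) -> ReferenceProfile:
    """Drop synthesized cells and project labels to the working level.

    The corpus must carry ``is_synthesized`` flags; ``required_types`` (the
    labels the mixtures to be deconvolved use) are checked to have at least
    one original cell each.
    """
    original = ~corpus.is_synthesized()
    kept = corpus.subset_cells(original.to_numpy())
    ref = ReferenceProfile(
        expression=pd.DataFrame(kept.X, index=kept.cell_ids, columns=kept.genes),
        labels=resolve_labels(kept, level).astype(str),
        patients=kept.obs["patient"].astype(str),
    )
    if required_types is not None:
        ref.require_types(required_types)
    return ref


def build_signature(
    ref: ReferenceProfile, top_markers: int | None = None
) -> SignatureMatrix:
    """Per-type mean expression, optionally restricted to top marker genes.

    With ``top_markers`` set, rows are the union over types of the
    ``top_markers`` genes with highest fold-change (type mean over mean of
    the other types, with a small pseudocount for stability).
    """
    types = ref.types
    if len(types) < 2:
        raise ValueError("signature needs at least two types")
    means = {}
    for t in types:
        cells = ref.labels == t
        if not cells.any():
            raise CorpusError(f"type {t!r} has no cells in the reference")
        means[t] = ref.expression.loc[cells.to_numpy()].mean(axis=0)
    sig = pd.DataFrame(means)  # genes x types, columns sorted by `types`
    if top_markers is not None:
        eps = 1e-9
        keep: set[str] = set()
        for t in types:
            others = sig.drop(columns=t).mean(axis=1)
            fold = (sig[t] + eps) / (others + eps)
            keep |= set(fold.nlargest(top_markers).index)
        sig = sig.loc[sorted(keep)]
    return SignatureMatrix(sig)


def marker_ranks(sig: SignatureMatrix) -> dict[str, pd.Series]:
    """Fold-change ranking of genes per type (largest first)."""
    out = {}
    eps = 1e-9
    for t in sig.types:
        others = sig.data.drop(columns=t).mean(axis=1)
        fold = (sig.data[t] + eps) / (others + eps)
        out[t] = fold.sort_values(ascending=False)
    return out
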