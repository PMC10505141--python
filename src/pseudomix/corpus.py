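"""Annotated single-cell corpus container and on-disk formats.

The central object of the package is :class:`AnnotatedCorpus`: a cells x genes
expression matrix (raw integer counts or CP10K-normalized reals) carried in an
:class:`anndata.AnnData`, with one row of per-cell metadata for each cell:
patient id, molecular subtype, and a three-level cell-type annotation
(``major`` > ``minor`` > ``subset``).

On disk a corpus is a directory in the conventional sparse triplet layout
(``matrix.mtx`` with genes as rows, ``genes.tsv``, ``barcodes.tsv``) plus a
``cells.tsv`` annotation table; tiny corpora can also round-trip through a
dense genes x cells CSV.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from pathlib import Path

LEVELS = ("major", "minor", "subset")

#: Reserved relabeling target that removes cells instead of renaming them.
DROP = "DROP"

_REQUIRED_OBS = ("patient", "major", "minor", "subset")


class CorpusError(ValueError):
    """Raised when a corpus violates its structural contract."""


class AnnotatedCorpus:
    """A genes-by-cells expression matrix with hierarchical cell annotations.

    Parameters
    ----------
    adata
        ``AnnData`` with cells as observations and genes as variables.
        ``obs`` must contain ``patient``, ``major``, ``minor`` and ``subset``
        columns; ``subtype`` (molecular subtype per patient) and
        ``is_synthesized`` are optional until the stages that need them.
    validate
        Check the structural invariants (unique cell ids, label nesting).
    """

    def __init__(self, adata: ad.AnnData, *, validate: bool = True):
        self.adata = adata
        if validate:
            self.validate()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray | sp.spmatrix,
        genes: Sequence[str],
        cell_table: pd.DataFrame,
    ) -> "AnnotatedCorpus":
        """Build a corpus from a cells x genes matrix and a cell table.

        ``cell_table`` must be indexed by cell id and carry the required
        annotation columns.
        """
        X = counts if sp.issparse(counts) else np.asarray(counts, dtype=np.float64)
        adata = ad.AnnData(
            X=X,
            obs=cell_table.copy(),
            var=pd.DataFrame(index=pd.Index(list(genes), name="gene")),
        )
        return cls(adata)

    # -- basic accessors ------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    @property
    def genes(self) -> pd.Index:
        return self.adata.var_names

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def obs(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def X(self) -> np.ndarray:
        """Dense cells x genes expression matrix."""
        X = self.adata.X
        return X.toarray() if sp.issparse(X) else np.asarray(X)

    @property
    def patients(self) -> list[str]:
        return sorted(self.obs["patient"].unique().tolist())

    def patient_subtypes(self) -> dict[str, str]:
        """Map patient id -> molecular subtype (empty if unannotated)."""
        if "subtype" not in self.obs:
            return {}
        return (
            self.obs.groupby("patient", observed=True)["subtype"]
            .first()
            .to_dict()
        )

    def labels(self, level: str) -> pd.Series:
        if level not in LEVELS:
            raise ValueError(f"unknown lineage level {level!r}; expected one of {LEVELS}")
        return self.obs[level]

    def is_synthesized(self) -> pd.Series:
        if "is_synthesized" not in self.obs:
            raise CorpusError("corpus carries no is_synthesized flags")
        return self.obs["is_synthesized"].astype(bool)

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        obs = self.adata.obs
        for col in _REQUIRED_OBS:
            if col not in obs.columns:
                raise CorpusError(f"cell table is missing required column {col!r}")
        if not obs.index.is_unique:
            dup = obs.index[obs.index.duplicated()][:3].tolist()
            raise CorpusError(f"cell ids are not unique (e.g. {dup})")
        X = self.adata.X
        data = X.data if sp.issparse(X) else X
        if data.size and float(np.min(data)) < 0:
            raise CorpusError("expression matrix contains negative values")
        self._check_nesting("minor", "major")
        self._check_nesting("subset", "minor")

    def _check_nesting(self, child: str, parent: str) -> None:
        table = self.obs[[child, parent]].drop_duplicates()
        bad = table[child][table[child].duplicated()]
        if len(bad):
            raise CorpusError(
                f"{child} label(s) {sorted(set(bad))} nest under more than one {parent} label"
            )

    # -- derived corpora ------------------------------------------------

    def subset_cells(self, mask: np.ndarray | pd.Series) -> "AnnotatedCorpus":
        """New corpus restricted to the cells selected by a boolean mask."""
        if isinstance(mask, pd.Series):
            mask = mask.reindex(self.adata.obs_names).to_numpy()
        return AnnotatedCorpus(self.adata[np.asarray(mask, dtype=bool)].copy(), validate=False)

    def subset_genes(self, genes: Iterable[str]) -> "AnnotatedCorpus":
        genes = list(genes)
        missing = set(genes) - set(self.adata.var_names)
        if missing:
            raise CorpusError(f"genes not in corpus: {sorted(missing)[:5]}")
        return AnnotatedCorpus(self.adata[:, genes].copy(), validate=False)

    def copy(self) -> "AnnotatedCorpus":
        return AnnotatedCorpus(self.adata.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AnnotatedCorpus({self.n_cells} cells x {self.n_genes} genes, "
            f"{len(self.patients)} patients)"
        )

    # -- I/O -------------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write MTX (genes x cells) + genes.tsv + barcodes.tsv + cells.tsv."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        X = self.adata.X
        mat = sp.csc_matrix(X.T if not sp.issparse(X) else X.T)
        scipy.io.mmwrite(str(path / "matrix.mtx"), mat)
        pd.Series(self.adata.var_names).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(self.adata.obs_names).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        self.adata.obs.to_csv(path / "cells.tsv", sep="\t", index_label="cell_id")

    @classmethod
    def from_dir(cls, path: str | Path) -> "AnnotatedCorpus":
        path = Path(path)
        mat = scipy.io.mmread(str(path / "matrix.mtx"))  # genes x cells
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(path / "cells.tsv", sep="\t", index_col="cell_id")
        cells.index = cells.index.astype(str)
        X = sp.csr_matrix(mat.T)
        return cls.from_arrays(X, genes, cells)

    def to_dense_csv(self, path: str | Path) -> None:
        """Dense genes x cells CSV, for tiny corpora only."""
        df = pd.DataFrame(self.X.T, index=self.adata.var_names, columns=self.adata.obs_names)
        df.to_csv(path, index_label="gene")
        Path(str(path) + ".cells.tsv").write_text(
            self.adata.obs.to_csv(sep="\t", index_label="cell_id")
        )

    @classmethod
    def from_dense_csv(cls, path: str | Path) -> "AnnotatedCorpus":
        df = pd.read_csv(path, index_col="gene")
        cells = pd.read_csv(str(path) + ".cells.tsv", sep="\t", index_col="cell_id")
        cells.index = cells.index.astype(str)
        return cls.from_arrays(df.to_numpy().T, df.index.tolist(), cells)


def resolve_labels(corpus: AnnotatedCorpus, level: str | Mapping[str, str]) -> pd.Series:
    """Per-cell working label at a lineage level, or a per-major mix of levels.

    ``level`` is either one of :data:`LEVELS`, applied to every cell, or a
    mapping ``major label -> level`` expanding selected major types to their
    minor/subset children while keeping the rest at major resolution (the
    lineage-granular mixture designs).
    """
    if isinstance(level, str):
        return corpus.labels(level).astype(str)
    majors = corpus.labels("major").astype(str)
    out = majors.copy()
    for major_label, lvl in level.items():
        if lvl not in LEVELS:
            raise ValueError(f"unknown lineage level {lvl!r} for {major_label!r}")
        mask = majors == major_label
        out[mask] = corpus.labels(lvl)[mask].astype(str)
    return out
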