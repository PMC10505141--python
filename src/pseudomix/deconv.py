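"""Deconvolution: an in-repo NNLS baseline and an external-method adapter.

The baseline solves, per mixture, the non-negative least-squares problem

    min || S w - b ||^2   s.t.  w >= 0

on the genes shared by the bulk profile ``b`` and the signature matrix ``S``
(per-type mean CP10K), and reports the renormalized weights as percentages.
It exercises the full framework end-to-end without external tools and gives
exact recovery on noiseless mixtures.

External methods (BayesPrism, Scaden, CIBERSORTx, MuSiC, DWLS, Bisque, CPM,
hspe, EPIC) are reached only through :func:`run_adapter`, a strict contract:
the adapter declares its executable, its input dialect (linear CP10K versus
``log2(x+1)``) and how to parse its output table; the framework materializes
the inputs, invokes the tool out of process, maps the output onto the
canonical type order, clips negative/NaN entries to zero (logged) and
renormalizes each row to 100.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import yaml

from .reference import SignatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class PredictionTable:
    """Mixtures x types predicted proportions on the percent scale."""

    data: pd.DataFrame
    method: str
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.data.to_numpy() < -1e-9).any():
            raise ValueError("prediction table contains negative proportions")
        sums = self.data.sum(axis=1)
        bad = sums[(sums - 100.0).abs() > 1e-6]
        if len(bad):
            raise ValueError(
                f"prediction rows do not sum to 100 (e.g. {bad.index[0]!r}: {bad.iloc[0]})"
            )

    def aligned_to(self, type_order: list[str]) -> "PredictionTable":
        """Reindex columns to the canonical truth order, zero-filling missing
        types (logged) and rejecting unknown ones."""
        unknown = set(self.data.columns) - set(type_order)
        if unknown:
            raise ValueError(f"prediction has unmappable type column(s): {sorted(unknown)}")
        missing = [t for t in type_order if t not in self.data.columns]
        if missing:
            warnings.warn(
                f"method {self.method!r} omitted type(s) {missing}; filled with 0",
                stacklevel=2,
            )
        return PredictionTable(
            data=self.data.reindex(columns=type_order, fill_value=0.0),
            method=self.method,
            provenance=dict(self.provenance),
        )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="mixture_id")

    @classmethod
    def from_tsv(cls, path, method: str = "external") -> "PredictionTable":
        return cls(pd.read_csv(path, sep="\t", index_col="mixture_id"), method=method)


def _renormalize(df: pd.DataFrame, method: str) -> pd.DataFrame:
    values = df.to_numpy(dtype=float)
    n_bad = int(np.sum(~np.isfinite(values)) + np.sum(values < 0))
    if n_bad:
        logger.warning("%s: clipped %d negative/NaN entries to 0", method, n_bad)
    values = np.where(np.isfinite(values), values, 0.0).clip(min=0.0)
    sums = values.sum(axis=1, keepdims=True)
    zero_rows = np.flatnonzero(sums.ravel() == 0)
    if zero_rows.size:
        warnings.warn(
            f"{method}: {zero_rows.size} all-zero prediction row(s); using uniform proportions",
            stacklevel=2,
        )
        values[zero_rows] = 1.0
        sums = values.sum(axis=1, keepdims=True)
    return pd.DataFrame(values / sums * 100.0, index=df.index, columns=df.columns)


def nnls_deconvolve(
    bulk: pd.DataFrame, sig: SignatureMatrix, method: str = "nnls"
) -> PredictionTable:
    """Non-negative least-squares baseline on the shared gene space.

    ``bulk`` is mixtures x genes (summed CP10K).  Deterministic, and
    invariant to gene ordering of either input.  A rank-deficient signature
    (two identical columns) is rejected up front.
    """
    shared = sorted(set(bulk.columns) & set(sig.genes))
    if len(shared) < len(sig.types):
        raise ValueError(
            f"only {len(shared)} shared genes for {len(sig.types)} types; cannot deconvolve"
        )
    S = sig.data.loc[shared].to_numpy(dtype=float)
    for i in range(S.shape[1]):
        for j in range(i + 1, S.shape[1]):
            if np.array_equal(S[:, i], S[:, j]):
                raise ValueError(
                    f"signature is rank-deficient: columns {sig.types[i]!r} and "
                    f"{sig.types[j]!r} are identical"
                )
    B = bulk[shared].to_numpy(dtype=float)
    W = np.empty((B.shape[0], S.shape[1]))
    for i in range(B.shape[0]):
        W[i], _ = scipy.optimize.nnls(S, B[i])
    raw = pd.DataFrame(W, index=bulk.index, columns=sig.types)
    out = PredictionTable(
        data=_renormalize(raw, method),
        method=method,
        provenance={"kind": "baseline", "n_shared_genes": len(shared)},
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# adapter contract for external methods
# ---------------------------------------------------------------------------

@dataclass
class AdapterConfig:
    """Declaration of one external deconvolution tool.

    ``command`` is a template whose placeholders ``{bulk}``, ``{reference}``,
    ``{labels}`` and ``{out}`` are substituted with materialized file paths.
    ``input_dialect`` selects the expression space the tool expects:
    ``linear`` (CP10K as-is) or ``log2p1`` (``log2(x+1)``, the hspe
    convention).  The output must be a TSV of mixtures x types proportions
    (any scale; rows are renormalized to 100).
    """

    name: str
    command: str
    input_dialect: str = "linear"
    input_format: str = "tsv"
    output_index_col: str = "mixture_id"

    def __post_init__(self):
        if self.input_dialect not in ("linear", "log2p1"):
            raise ValueError(f"unknown input dialect {self.input_dialect!r}")
        if self.input_format != "tsv":
            raise ValueError("only the tsv input format is implemented")

    @classmethod
    def from_yaml(cls, path) -> "AdapterConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def transform_dialect(df: pd.DataFrame, dialect: str) -> pd.DataFrame:
    if dialect == "linear":
        return df
    return np.log2(df + 1.0)


def inverse_dialect(df: pd.DataFrame, dialect: str) -> pd.DataFrame:
    if dialect == "linear":
        return df
    return np.exp2(df) - 1.0


def run_adapter(
    bulk: pd.DataFrame,
    reference_expression: pd.DataFrame,
    reference_labels: pd.Series,
    config: AdapterConfig,
    type_order: list[str] | None = None,
    workdir: str | Path | None = None,
) -> PredictionTable:
    """Invoke an external deconvolution method under the adapter contract.

    Inputs are written in the declared dialect; a non-zero exit status
    surfaces the captured stderr.  The parsed output is clipped, aligned to
    ``type_order`` (missing types zero-filled with a warning) and
    renormalized so every row sums to 100.
    """
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    root = Path(workdir) if workdir is not None else Path(ctx.name)
    try:
        root.mkdir(parents=True, exist_ok=True)
        bulk_path = root / "bulk.tsv"
        ref_path = root / "reference.tsv"
        labels_path = root / "labels.tsv"
        out_path = root / "predictions.tsv"
        transform_dialect(bulk, config.input_dialect).to_csv(
            bulk_path, sep="\t", index_label="mixture_id"
        )
        transform_dialect(reference_expression, config.input_dialect).to_csv(
            ref_path, sep="\t", index_label="cell_id"
        )
        reference_labels.rename("type").to_csv(labels_path, sep="\t", index_label="cell_id")
        cmd = config.command.format(
            bulk=bulk_path, reference=ref_path, labels=labels_path, out=out_path
        )
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"adapter {config.name!r} failed (exit {proc.returncode}):\n{proc.stderr}"
            )
        raw = pd.read_csv(out_path, sep="\t", index_col=config.output_index_col)
    finally:
        if ctx is not None:
            ctx.cleanup()
    table = PredictionTable(
        data=raw, method=config.name,
        provenance={"kind": "adapter", "command": config.command,
                    "dialect": config.input_dialect},
    )
    if type_order is not None:
        table = table.aligned_to(type_order)
    table = PredictionTable(
        data=_renormalize(table.data, config.name),
        method=table.method, provenance=table.provenance,
    )
    table.validate()
    return table
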