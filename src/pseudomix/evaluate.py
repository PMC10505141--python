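"""Scoring of predicted against true cell-type compositions.

All metrics operate on the percent scale (rows summing to 100).  Because
every mixture contains exactly 500 cells, percentages and cell counts are
equivalent up to a constant, so the count-based Bray-Curtis definition and
the percentage one coincide.

Compositional metrics (whole-mixture):

* Bray-Curtis dissimilarity: ``1 - 2 * sum_i min(p_i, t_i) / (sum p + sum t)``,
  in [0, 1], zero iff the compositions are equal.
* Aitchison distance: Euclidean distance between centred log-ratio (CLR)
  transforms.  Zeros are handled by an additive pseudocount on the unit
  simplex followed by re-closure (configurable), since both predictions and
  truths legitimately contain exact zeros.

Cell-type-specific metrics (per component): RMSE and Pearson's r per
(type, group) with medians across groups; signed raw errors (pred - truth),
kept as distributions and never averaged; Relative Proportion Error
``|pred - truth| / truth`` defined only where truth > 0; and a
presence/absence confusion analysis at a 0.1% threshold with severity bins
[0.1, 1), [1, 10), [10, inf) percent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

PRESENCE_THRESHOLD = 0.1  # percent
SEVERITY_BINS = ((0.1, 1.0), (1.0, 10.0), (10.0, np.inf))
SEVERITY_LABELS = ("0.1-1%", "1-10%", ">10%")


# ---------------------------------------------------------------------------
# compositional metrics
# ---------------------------------------------------------------------------

def bray_curtis(pred: np.ndarray, truth: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two compositions (percent scale)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    denom = pred.sum() + truth.sum()
    return float(1.0 - 2.0 * np.minimum(pred, truth).sum() / denom)


def clr(composition: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    """Centred log-ratio transform with additive zero replacement.

    The composition is closed to the unit simplex, zeros receive an additive
    pseudocount (default 1e-6) followed by re-closure, then each part is
    log-divided by the geometric mean.  The output sums to zero.
    """
    x = np.asarray(composition, dtype=float)
    if (x < 0).any():
        raise ValueError("composition entries must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("cannot CLR-transform an all-zero composition")
    x = x / total
    if (x == 0).any():
        x = x + pseudocount
        x = x / x.sum()
    logx = np.log(x)
    return logx - logx.mean()


def aitchison_distance(
    pred: np.ndarray, truth: np.ndarray, pseudocount: float = 1e-6
) -> float:
    """Euclidean distance between the CLR transforms of two compositions."""
    return float(
        np.linalg.norm(clr(pred, pseudocount) - clr(truth, pseudocount))
    )


def mixture_metrics(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    groups: pd.DataFrame | None = None,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Per-mixture Bray-Curtis and Aitchison distance.

    ``pred`` and ``truth`` are mixtures x types (percent) with matching
    indices and columns; ``groups`` optionally supplies per-mixture keys
    (donor, purity, ...) that are carried through.
    """
    pred, truth = _align(pred, truth)
    P, T = pred.to_numpy(), truth.to_numpy()
    rows = {
        "bray_curtis": [bray_curtis(P[i], T[i]) for i in range(len(P))],
        "aitchison": [aitchison_distance(P[i], T[i], pseudocount) for i in range(len(P))],
    }
    out = pd.DataFrame(rows, index=pred.index)
    if groups is not None:
        out = out.join(groups, how="left")
    return out


def _align(pred: pd.DataFrame, truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(pred.index) != set(truth.index):
        raise ValueError("prediction and truth mixture ids do not match")
    if set(pred.columns) != set(truth.columns):
        raise ValueError("prediction and truth type columns do not match")
    pred = pred.loc[truth.index, truth.columns]
    return pred, truth


# ---------------------------------------------------------------------------
# long-format error table
# ---------------------------------------------------------------------------

def build_error_table(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    groups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format per-(mixture, type) records with raw error and RPE.

    ``raw_error = pred - truth`` (signed, percentage points); ``rpe`` is
    ``|pred - truth| / truth`` where truth > 0 and NaN otherwise.
    """
    pred, truth = _align(pred, truth)
    long = (
        pd.concat(
            {"pred": pred.stack(), "truth": truth.stack()}, axis=1
        )
        .rename_axis(["mixture_id", "type"])
        .reset_index()
    )
    long["raw_error"] = long["pred"] - long["truth"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rpe = np.abs(long["raw_error"]) / long["truth"]
    long["rpe"] = rpe.where(long["truth"] > 0)
    if groups is not None:
        long = long.merge(groups, left_on="mixture_id", right_index=True, how="left")
    return long


def per_type_accuracy(
    errors: pd.DataFrame, group_by: Sequence[str] = ()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RMSE and Pearson's r per (type, group) plus median-over-groups summary.

    Pearson's r is undefined for groups whose truth has zero variance; such
    groups are excluded from the median (and counted in the summary).
    """
    errors = errors.copy()
    group_by = list(group_by)
    if not group_by:
        errors["_all"] = "all"
        group_by = ["_all"]
    records = []
    for keys, grp in errors.groupby(["type", *group_by], observed=True, dropna=False):
        if grp.empty:
            continue
        t = keys[0] if isinstance(keys, tuple) else keys
        rmse = float(np.sqrt(np.mean(grp["raw_error"] ** 2)))
        truth = grp["truth"].to_numpy()
        if len(grp) >= 2 and np.ptp(truth) > 0 and np.ptp(grp["pred"].to_numpy()) > 0:
            r = float(scipy.stats.pearsonr(grp["pred"], grp["truth"])[0])
        else:
            r = np.nan
        rec = {"type": t, "rmse": rmse, "pearson_r": r, "n": len(grp)}
        extra = keys[1:] if isinstance(keys, tuple) else ()
        rec.update(dict(zip(group_by, extra)))
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    n_undef = (
        table.assign(undef=table["pearson_r"].isna())
        .groupby("type", observed=True)["undef"].sum()
    )
    if int(n_undef.sum()):
        logger.info("Pearson's r undefined in %d (type, group) cell(s); excluded from medians",
                    int(n_undef.sum()))
    summary = (
        table.groupby("type", observed=True)
        .agg(
            median_rmse=("rmse", "median"),
            median_pearson_r=("pearson_r", "median"),
            n_groups=("rmse", "size"),
        )
        .join(n_undef.rename("n_undefined_r"))
        .reset_index()
    )
    return table, summary


def rpe_table(
    errors: pd.DataFrame, group_by: Sequence[str] = ()
) -> pd.DataFrame:
    """Median and max Relative Proportion Error per (type, group).

    Components with truth == 0 have no defined RPE; they are counted in
    ``n_undefined`` rather than silently dropped.
    """
    errors = errors.copy()
    group_by = list(group_by)
    if not group_by:
        errors["_all"] = "all"
        group_by = ["_all"]
    out = (
        errors.groupby(["type", *group_by], observed=True, dropna=False)
        .agg(
            median_rpe=("rpe", "median"),
            max_rpe=("rpe", "max"),
            n_defined=("rpe", "count"),
            n_total=("rpe", "size"),
        )
        .reset_index()
    )
    out["n_undefined"] = out["n_total"] - out["n_defined"]
    return out.drop(columns="n_total")


# ---------------------------------------------------------------------------
# presence/absence confusion analysis
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    """Presence/absence confusion counts with FP/FN severity histograms.

    A (mixture, type) component with truth below the presence threshold is an
    actual negative: predicted below threshold is a true negative, otherwise
    a false positive binned by its *predicted* value.  A component with truth
    at or above threshold is an actual positive: predicted below threshold is
    a false negative binned by its *truth* value, otherwise a true positive.
    ``fp_rate = FP / (FP + TN)``; ``fn_rate = FN / (FN + TP)``.
    """

    per_type: pd.DataFrame  # index: type; TP/TN/FP/FN + rates
    fp_bins: pd.DataFrame  # type x severity bin
    fn_bins: pd.DataFrame
    threshold: float
    excluded_types: tuple[str, ...] = ()

    @property
    def overall(self) -> pd.Series:
        counts = self.per_type[["TP", "TN", "FP", "FN"]].sum()
        fp_tn = counts["FP"] + counts["TN"]
        fn_tp = counts["FN"] + counts["TP"]
        counts["fp_rate"] = counts["FP"] / fp_tn if fp_tn else np.nan
        counts["fn_rate"] = counts["FN"] / fn_tp if fn_tp else np.nan
        return counts

    @property
    def n_components(self) -> int:
        return int(self.per_type[["TP", "TN", "FP", "FN"]].to_numpy().sum())

    def to_dict(self) -> dict:
        overall = self.overall
        return {
            "threshold_percent": self.threshold,
            "excluded_types": list(self.excluded_types),
            "n_components": self.n_components,
            "overall": {k: (None if pd.isna(v) else float(v)) for k, v in overall.items()},
            "per_type": json.loads(self.per_type.to_json(orient="index")),
            "fp_bins": json.loads(self.fp_bins.to_json(orient="index")),
            "fn_bins": json.loads(self.fn_bins.to_json(orient="index")),
        }


def _severity_bin(values: pd.Series) -> pd.Categorical:
    # lower-inclusive bins [0.1,1), [1,10), [10,inf)
    edges = [SEVERITY_BINS[0][0], SEVERITY_BINS[1][0], SEVERITY_BINS[2][0], np.inf]
    return pd.cut(values, bins=edges, labels=SEVERITY_LABELS, right=False)


def confusion_analysis(
    errors: pd.DataFrame,
    presence_threshold: float = PRESENCE_THRESHOLD,
    exclude_types: set[str] | None = None,
) -> ConfusionSummary:
    """Classify every scored (mixture, type) component as TP/TN/FP/FN.

    ``exclude_types`` removes types whose presence is fixed by design (the
    cancer label in fixed-purity experiments) before counting.
    """
    if presence_threshold <= 0:
        raise ValueError("presence threshold must be positive")
    df = errors
    excluded = tuple(sorted(exclude_types)) if exclude_types else ()
    if excluded:
        df = df[~df["type"].isin(excluded)]
    thr = presence_threshold
    actual_neg = df["truth"] < thr
    pred_neg = df["pred"] < thr
    outcome = np.where(
        actual_neg,
        np.where(pred_neg, "TN", "FP"),
        np.where(pred_neg, "FN", "TP"),
    )
    df = df.assign(outcome=outcome)
    counts = (
        df.groupby(["type", "outcome"], observed=True).size().unstack(fill_value=0)
        .reindex(columns=["TP", "TN", "FP", "FN"], fill_value=0)
    )
    fp_tn = counts["FP"] + counts["TN"]
    fn_tp = counts["FN"] + counts["TP"]
    counts["fp_rate"] = np.where(fp_tn > 0, counts["FP"] / fp_tn.replace(0, np.nan), np.nan)
    counts["fn_rate"] = np.where(fn_tp > 0, counts["FN"] / fn_tp.replace(0, np.nan), np.nan)

    fp = df[df["outcome"] == "FP"]
    fn = df[df["outcome"] == "FN"]
    fp_bins = (
        fp.assign(bin=_severity_bin(fp["pred"]))
        .groupby(["type", "bin"], observed=False).size().unstack(fill_value=0)
        .reindex(index=counts.index, fill_value=0)
    )
    fn_bins = (
        fn.assign(bin=_severity_bin(fn["truth"]))
        .groupby(["type", "bin"], observed=False).size().unstack(fill_value=0)
        .reindex(index=counts.index, fill_value=0)
    )
    for bins, col in ((fp_bins, "FP"), (fn_bins, "FN")):
        mismatch = bins.sum(axis=1) != counts[col]
        if mismatch.any():  # pragma: no cover - internal consistency guard
            raise AssertionError(f"severity histogram does not sum to {col} counts")
    return ConfusionSummary(
        per_type=counts, fp_bins=fp_bins, fn_bins=fn_bins,
        threshold=thr, excluded_types=excluded,
    )


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Machine-readable summaries for a set of prediction tables."""

    mixture_metrics: pd.DataFrame  # method, mixture, bray_curtis, aitchison (+groups)
    ranking: pd.DataFrame  # methods ordered by increasing median Bray-Curtis
    per_type: pd.DataFrame  # method, type, group, rmse, pearson_r
    per_type_summary: pd.DataFrame
    rpe: pd.DataFrame
    confusion: dict[str, ConfusionSummary]
    immune_aitchison: pd.DataFrame | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def immune_only_aitchison(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    immune_types: Sequence[str],
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Aitchison distance on the re-closed immune sub-composition.

    Mixtures with zero immune mass in the truth have no defined immune
    sub-composition and are excluded (logged).
    """
    pred, truth = _align(pred, truth)
    cols = [t for t in immune_types if t in truth.columns]
    P, T = pred[cols].to_numpy(), truth[cols].to_numpy()
    ok = (T.sum(axis=1) > 0) & (P.sum(axis=1) > 0)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("immune-only Aitchison: excluded %d mixture(s) with zero immune mass", n_skip)
    vals = [
        aitchison_distance(P[i], T[i], pseudocount)
        for i in np.flatnonzero(ok)
    ]
    return pd.DataFrame(
        {"immune_aitchison": vals}, index=pred.index[np.asarray(ok, bool)]
    )


def report(
    predictions: list,
    truth: pd.DataFrame,
    groups: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    group_by: Sequence[str] = ("donor", "purity"),
    exclude_types: set[str] | None = None,
    immune_types: Sequence[str] | None = None,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> EvaluationReport:
    """Score one or more prediction tables against a shared ground truth.

    Emits per-mixture compositional distances, per-type RMSE/Pearson tables
    grouped by the requested keys, RPE summaries, confusion summaries, a
    method ranking by median Bray-Curtis (best first), and optionally the
    immune-only Aitchison variant.  With ``outdir`` set, everything is also
    written as TSV/JSON.
    """
    group_by = [g for g in group_by if groups is not None and g in groups.columns]
    mm_frames, pt_frames, pts_frames, rpe_frames = [], [], [], []
    confusion: dict[str, ConfusionSummary] = {}
    immune_frames = []
    for table in predictions:
        pred = table.aligned_to(list(truth.columns)).data
        mm = mixture_metrics(pred, truth, groups).assign(method=table.method)
        mm_frames.append(mm)
        errs = build_error_table(pred, truth, groups)
        pt, pts = per_type_accuracy(errs, group_by)
        pt_frames.append(pt.assign(method=table.method))
        pts_frames.append(pts.assign(method=table.method))
        rpe_frames.append(rpe_table(errs, group_by).assign(method=table.method))
        confusion[table.method] = confusion_analysis(
            errs, presence_threshold, exclude_types
        )
        if immune_types:
            immune_frames.append(
                immune_only_aitchison(pred, truth, immune_types).assign(method=table.method)
            )
    mixture_df = pd.concat(mm_frames)
    ranking = (
        mixture_df.groupby("method")["bray_curtis"].median()
        .sort_values()
        .rename("median_bray_curtis")
        .reset_index()
    )
    rep = EvaluationReport(
        mixture_metrics=mixture_df,
        ranking=ranking,
        per_type=pd.concat(pt_frames, ignore_index=True),
        per_type_summary=pd.concat(pts_frames, ignore_index=True),
        rpe=pd.concat(rpe_frames, ignore_index=True),
        confusion=confusion,
        immune_aitchison=pd.concat(immune_frames) if immune_frames else None,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        writes = {
            "mixture_metrics.tsv": rep.mixture_metrics,
            "method_ranking.tsv": rep.ranking,
            "per_type_accuracy.tsv": rep.per_type,
            "per_type_summary.tsv": rep.per_type_summary,
            "rpe_summary.tsv": rep.rpe,
        }
        if rep.immune_aitchison is not None:
            writes["immune_aitchison.tsv"] = rep.immune_aitchison
        for name, frame in writes.items():
            path = outdir / name
            frame.to_csv(path, sep="\t", index=name == "mixture_metrics.tsv"
                         or name == "immune_aitchison.tsv")
            rep.paths[name] = path
        conf_path = outdir / "confusion.json"
        conf_path.write_text(
            json.dumps({m: c.to_dict() for m, c in confusion.items()}, indent=2)
        )
        rep.paths["confusion.json"] = conf_path
    return rep
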