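"""Per-patient SMOTE balancing of cell-type abundances.

Within each patient, every retained cell type is augmented up to the cell
count of that patient's most abundant type, so that subsequent mixture
sampling can draw any type at any proportion without re-using cells.  A
synthesized cell is a convex combination of two original cells of the same
patient and type:

    x_new = x_i + lam * (x_j - x_i),   lam ~ Uniform[0, 1]

with the partner x_j chosen uniformly among the other original cells of the
group.  Synthesis never crosses patient or type boundaries, and a type
absent in a patient stays absent.  Each synthesized cell records its two
parents and its lam, so it can be reconstructed exactly from the corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Mapping

import numpy as np
import pandas as pd

from .corpus import AnnotatedCorpus, CorpusError, resolve_labels


@dataclass
class SmoteReport:
    """Per-patient bookkeeping of the balancing step."""

    patient: str
    seed: int
    #: one row per retained type: original_count, synthesized_count, target_count
    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if len(t) and not (
            (t["target_count"] == t["original_count"] + t["synthesized_count"]).all()
            and (t["synthesized_count"] >= 0).all()
        ):
            raise ValueError("inconsistent SMOTE report counts")


def patient_seed(cohort_seed: int, patient: str) -> int:
    """Deterministic per-patient sub-seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(cohort_seed), *patient.encode("utf8")])
    return int(ss.generate_state(1)[0] % (2**31))


def smote_patient(
    corpus: AnnotatedCorpus,
    patient: str,
    rng_seed: int,
    level: str | Mapping[str, str] = "major",
) -> tuple[AnnotatedCorpus, SmoteReport]:
    """Balance one patient's cell types to the patient's maximum count.

    Expects a normalized, rare-filtered corpus; every retained type must have
    at least 2 cells (interpolation is degenerate below that).  Original
    cells are untouched; synthesized cells carry ``is_synthesized=True`` plus
    ``parent_a``/``parent_b``/``smote_lambda`` provenance columns.
    """
    if patient not in set(corpus.patients):
        raise CorpusError(f"patient {patient!r} not in corpus")
    rng = np.random.default_rng(rng_seed)
    obs = corpus.obs
    mask = (obs["patient"] == patient).to_numpy()
    labels = resolve_labels(corpus, level).astype(str).to_numpy()
    X = corpus.X

    groups = {
        t: np.flatnonzero(mask & (labels == t))
        for t in pd.unique(labels[mask])
    }
    target = max(len(ix) for ix in groups.values())

    rows = []
    new_blocks: list[np.ndarray] = []
    new_records: list[dict] = []
    for t in sorted(groups):
        ix = groups[t]
        need = target - len(ix)
        rows.append(
            {
                "patient": patient,
                "type": t,
                "original_count": len(ix),
                "synthesized_count": need,
                "target_count": target,
            }
        )
        if need == 0:
            continue
        if len(ix) < 2:
            raise CorpusError(
                f"type {t!r} of patient {patient!r} has {len(ix)} cell(s); "
                "cannot interpolate (should have been filtered upstream)"
            )
        a = rng.integers(0, len(ix), size=need)
        # partner uniform over the *other* cells of the group
        b = (a + rng.integers(1, len(ix), size=need)) % len(ix)
        lam = rng.uniform(size=need)
        Xa, Xb = X[ix[a]], X[ix[b]]
        new_blocks.append(Xa + lam[:, None] * (Xb - Xa))
        ids = corpus.cell_ids.to_numpy()
        parent_obs = obs.iloc[ix[a]]
        for k in range(need):
            rec = parent_obs.iloc[k].to_dict()
            rec.update(
                cell_id=f"{patient}|synth|{t}|{k}",
                is_synthesized=True,
                parent_a=ids[ix[a][k]],
                parent_b=ids[ix[b][k]],
                smote_lambda=lam[k],
            )
            new_records.append(rec)

    report = SmoteReport(
        patient=patient,
        seed=int(rng_seed),
        table=pd.DataFrame.from_records(rows),
    )
    base = corpus.subset_cells(mask)
    base_obs = base.adata.obs
    if "parent_a" not in base_obs:
        base_obs = base_obs.assign(parent_a="", parent_b="", smote_lambda=np.nan)
    if "is_synthesized" not in base_obs:
        base_obs = base_obs.assign(is_synthesized=False)
    if not new_records:
        out = AnnotatedCorpus.from_arrays(base.X, list(corpus.genes), base_obs)
        return out, report
    new_obs = pd.DataFrame.from_records(new_records).set_index("cell_id")
    all_obs = pd.concat([base_obs, new_obs.reindex(columns=base_obs.columns)])
    all_X = np.vstack([base.X, np.vstack(new_blocks)])
    out = AnnotatedCorpus.from_arrays(all_X, list(corpus.genes), all_obs)
    return out, report


def oversample_cohort(
    corpus: AnnotatedCorpus, rng_seed: int, level: str | Mapping[str, str] = "major"
) -> tuple[AnnotatedCorpus, list[SmoteReport]]:
    """Run :func:`smote_patient` independently for every patient.

    Sub-seeds are derived deterministically from ``rng_seed`` and the patient
    id, so the cohort result is reproducible and order-independent.  A type
    missing from a patient is not synthesized for that patient.
    """
    pieces: list[AnnotatedCorpus] = []
    reports: list[SmoteReport] = []
    for patient in corpus.patients:
        sub_seed = patient_seed(rng_seed, patient)
        aug, rep = smote_patient(corpus, patient, sub_seed, level=level)
        pieces.append(aug)
        reports.append(rep)
    obs = pd.concat([p.adata.obs for p in pieces])
    X = np.vstack([p.X for p in pieces])
    out = AnnotatedCorpus.from_arrays(X, list(corpus.genes), obs)
    return out, reports


def replay_synthesized(corpus: AnnotatedCorpus) -> np.ndarray:
    """Recompute every synthesized cell from its stored parents and lambda.

    Returns the reconstructed (n_synth x n_genes) matrix in corpus order;
    equality with the stored rows verifies provenance integrity.
    """
    obs = corpus.obs
    synth = corpus.is_synthesized().to_numpy()
    if not synth.any():
        return np.empty((0, corpus.n_genes))
    pos = {cid: i for i, cid in enumerate(corpus.cell_ids)}
    ia = [pos[c] for c in obs.loc[synth, "parent_a"]]
    ib = [pos[c] for c in obs.loc[synth, "parent_b"]]
    lam = obs.loc[synth, "smote_lambda"].to_numpy(dtype=float)
    X = corpus.X
    return X[ia] + lam[:, None] * (X[ib] - X[ia])
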