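"""Simulation of artificial bulk RNA-seq mixtures with known composition.

Every mixture is the sum of the CP10K expression vectors of exactly 500
single cells drawn, without replacement within the mixture, from one donor's
(SMOTE-augmented) cell pool.  Three designs are provided:

* **sparse training mixtures** -- a random number of the donor's cell types
  (at least 5 where available) is included; one randomly chosen "free-range"
  type receives an unconstrained Uniform(0,1) share and the remaining
  included types split the residual proportionally to i.i.d. Uniform(0,1)
  draws.  This yields a far wider per-type proportion range than naive
  resampling.
* **tumour-purity series** -- the cancer-epithelial fraction is pinned to
  each value of a 19-level grid (5%..95% in 5% steps) while everything else
  is randomized as above.
* **lineage-granular mixtures** -- selected major types are replaced by
  their minor/subset children (e.g. the three normal-epithelial minors, or
  the 23 immune subsets), optionally at a fixed 50% tumour purity and with
  selected labels excluded from the available pool.

Planning (which types, fractions, integer cell counts, ground truth) is
separable from assembly (which actual cells, summed expression): a plan is
fully determined by the donors' available type lists and the seed, so design
arithmetic is reproducible without touching expression data.  Ground truth
is defined from the realized integer counts (counts/500, on the percent
scale), since the 500 sampled cells are the physical truth of a pseudobulk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import AnnotatedCorpus, resolve_labels

logger = logging.getLogger(__name__)

MIXTURE_SIZE = 500
DEFAULT_PURITY_GRID = tuple(np.round(np.arange(5, 100, 5) / 100.0, 2))  # 0.05..0.95
CANCER_LABEL = "cancer_epithelial"


@dataclass
class MixtureSpec:
    """Recipe for one mixture: donor, types, fractions, integer counts."""

    mixture_id: str
    donor: str
    included_types: tuple[str, ...]
    free_type: str | None
    fractions: dict[str, float]
    counts: dict[str, int]
    purity: float | None
    seed: int
    #: filled at assembly: type -> tuple of selected cell ids
    selected_cells: dict[str, tuple[str, ...]] | None = None

    def validate(self) -> None:
        total_f = sum(self.fractions.values())
        if abs(total_f - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total_f}, not 1")
        if sum(self.counts.values()) != MIXTURE_SIZE:
            raise ValueError("counts do not sum to the mixture size")
        if (
            self.purity is not None
            and CANCER_LABEL in self.fractions
            and abs(self.fractions[CANCER_LABEL] - self.purity) > 1e-9
        ):
            raise ValueError("cancer fraction does not match the fixed purity")

    def truth_row(self, label_universe: Sequence[str]) -> pd.Series:
        """Realized ground-truth proportions (percent) over a label universe."""
        return pd.Series(
            {t: 100.0 * self.counts.get(t, 0) / MIXTURE_SIZE for t in label_universe},
            name=self.mixture_id,
        )


@dataclass
class PseudobulkSet:
    """Mixtures x genes expression plus mixtures x types ground truth."""

    expression: pd.DataFrame | None
    truth: pd.DataFrame  # percent scale, rows sum to 100
    specs: list[MixtureSpec]
    metadata: dict = field(default_factory=dict)

    @property
    def n_mixtures(self) -> int:
        return len(self.specs)

    def groups(self) -> pd.DataFrame:
        """Per-mixture grouping keys (donor, purity) for evaluation."""
        return pd.DataFrame(
            {
                "mixture_id": [s.mixture_id for s in self.specs],
                "donor": [s.donor for s in self.specs],
                "purity": [s.purity for s in self.specs],
            }
        ).set_index("mixture_id")


# ---------------------------------------------------------------------------
# fraction drawing and count rounding
# ---------------------------------------------------------------------------

def draw_sparse_fractions(
    available_types: Sequence[str],
    fixed: tuple[str, float] | None = None,
    min_types: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[str, dict[str, float]]:
    """Draw one mixture's cell-type fractions under the sparse design.

    The number of included types k is uniform on
    [min(min_types, n_available), n_available]; a donor with fewer than
    ``min_types`` available types degrades to using all of them.  ``fixed``
    pins one label (the cancer type in purity designs) to an exact fraction
    in (0,1); the free-range type is always drawn among the non-fixed
    included types.  Types not included get fraction 0; the result sums to 1.
    """
    rng = np.random.default_rng() if rng is None else rng
    types = list(available_types)
    n = len(types)
    if n == 0:
        raise ValueError("no available cell types to draw from")
    fractions = {t: 0.0 for t in types}

    if fixed is not None:
        fixed_label, fixed_frac = fixed
        if fixed_label not in fractions:
            raise ValueError(f"fixed label {fixed_label!r} not among available types")
        if not (0.0 < fixed_frac < 1.0):
            raise ValueError("fixed fraction must lie strictly inside (0, 1)")
        others = [t for t in types if t != fixed_label]
        if not others:
            raise ValueError("fixed-purity design needs at least one non-fixed type")
        k = int(rng.integers(min(min_types, n), n + 1))
        k = max(k, 2)  # the fixed label plus at least one free type
        chosen_others = list(rng.choice(others, size=k - 1, replace=False))
        fractions[fixed_label] = fixed_frac
        budget = 1.0 - fixed_frac
        nonfixed = chosen_others
    else:
        k = int(rng.integers(min(min_types, n), n + 1))
        nonfixed = list(rng.choice(types, size=k, replace=False))
        budget = 1.0

    free_type = str(rng.choice(nonfixed))
    rest = [t for t in nonfixed if t != free_type]
    if not rest:
        fractions[free_type] = budget
        return free_type, fractions
    f_free = float(rng.uniform()) * budget
    fractions[free_type] = f_free
    r = rng.uniform(size=len(rest))
    r = r / r.sum() * (budget - f_free)
    for t, f in zip(rest, r):
        fractions[t] = float(f)
    return free_type, fractions


def fractions_to_counts(
    fractions: Mapping[str, float], total: int = MIXTURE_SIZE
) -> dict[str, int]:
    """Largest-remainder rounding of fraction*total to integers summing to
    ``total``; remainder ties are broken by earliest position."""
    if total <= 0:
        raise ValueError("total must be positive")
    labels = list(fractions)
    f = np.array([fractions[t] for t in labels], dtype=float)
    if (f < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {f.sum()}, not 1")
    raw = f * total
    floors = np.floor(raw).astype(int)
    leftover = total - int(floors.sum())
    remainders = raw - floors
    order = np.argsort(-remainders, kind="stable")  # stable => earliest wins ties
    counts = floors.copy()
    counts[order[:leftover]] += 1
    return {t: int(c) for t, c in zip(labels, counts)}


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

def _mixture_seed(cohort_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(cohort_seed), int(index)]).generate_state(1)[0] % (2**31))


def plan_mixtures(
    donor_types: Mapping[str, Sequence[str]],
    donors: Sequence[str],
    per_donor: int,
    seed: int,
    *,
    fixed_label: str | None = None,
    fixed_fraction: float | None = None,
    min_types: int = 5,
    id_prefix: str = "mix",
) -> list[MixtureSpec]:
    """Plan ``per_donor`` mixtures for each donor from its available types."""
    specs: list[MixtureSpec] = []
    idx = 0
    for donor in donors:
        available = list(donor_types[donor])
        if len(available) < min_types:
            logger.info(
                "donor %s has only %d available types (< %d); using all of them",
                donor, len(available), min_types,
            )
        for _ in range(per_donor):
            sub_seed = _mixture_seed(seed, idx)
            rng = np.random.default_rng(sub_seed)
            fixed = None
            if fixed_label is not None:
                fixed = (fixed_label, float(fixed_fraction))
            free_type, fractions = draw_sparse_fractions(
                available, fixed=fixed, min_types=min_types, rng=rng
            )
            counts = fractions_to_counts(fractions)
            spec = MixtureSpec(
                mixture_id=f"{id_prefix}{idx:06d}",
                donor=donor,
                included_types=tuple(t for t, f in fractions.items() if f > 0),
                free_type=free_type,
                fractions=fractions,
                counts=counts,
                purity=fixed_fraction,
                seed=sub_seed,
            )
            spec.validate()
            specs.append(spec)
            idx += 1
    return specs


def plan_purity_series(
    donor_types: Mapping[str, Sequence[str]],
    donors: Sequence[str],
    purity_grid: Sequence[float] = DEFAULT_PURITY_GRID,
    per_donor_per_level: int = 250,
    seed: int = 0,
    cancer_label: str = CANCER_LABEL,
) -> list[MixtureSpec]:
    """Plan the fixed-purity test design from donors' available types alone.

    The mixture count (donors x grid levels x per-donor) and every recorded
    ground truth follow from the plan without touching expression data.
    """
    for d in donors:
        if cancer_label not in donor_types[d]:
            raise ValueError(f"donor {d!r} has no {cancer_label!r} cells")
    specs: list[MixtureSpec] = []
    for li, p in enumerate(purity_grid):
        specs.extend(
            plan_mixtures(
                donor_types, list(donors), per_donor_per_level,
                _mixture_seed(seed, li),
                fixed_label=cancer_label, fixed_fraction=float(p),
                id_prefix=f"pur{int(round(p * 100)):02d}_",
            )
        )
    return specs


def donor_available_types(
    corpus: AnnotatedCorpus, level: str | Mapping[str, str], donors: Sequence[str] | None = None
) -> dict[str, list[str]]:
    """Map donor -> sorted list of working-level labels with >=1 cell."""
    labels = resolve_labels(corpus, level)
    table = pd.DataFrame({"patient": corpus.obs["patient"], "label": labels})
    out: dict[str, list[str]] = {}
    for donor, grp in table.groupby("patient", observed=True):
        out[str(donor)] = sorted(grp["label"].unique())
    if donors is not None:
        missing = set(donors) - set(out)
        if missing:
            raise ValueError(f"donors not in corpus: {sorted(missing)}")
        out = {d: out[d] for d in donors}
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_mixture(
    corpus: AnnotatedCorpus,
    spec: MixtureSpec,
    rng: np.random.Generator,
    *,
    level: str | Mapping[str, str] = "major",
    label_universe: Sequence[str] | None = None,
    _pools: Mapping[tuple[str, str], np.ndarray] | None = None,
    _X: np.ndarray | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Sample the spec's cells from the donor pool and sum their expression.

    Cells are drawn uniformly without replacement within the mixture, per
    type, from the donor's pool (original + synthesized cells).  Returns the
    summed expression vector and the realized ground-truth row (percent).
    """
    X = corpus.X if _X is None else _X
    if _pools is None:
        labels = resolve_labels(corpus, level).to_numpy()
        patients = corpus.obs["patient"].to_numpy()
        _pools = {
            (spec.donor, t): np.flatnonzero((patients == spec.donor) & (labels == t))
            for t in spec.counts
        }
    chosen: list[int] = []
    provenance: dict[str, tuple[str, ...]] = {}
    ids = corpus.cell_ids
    for t, n in spec.counts.items():
        if n == 0:
            continue
        pool = _pools[(spec.donor, t)]
        if len(pool) < n:
            raise ValueError(
                f"pool shortfall for donor {spec.donor!r}, type {t!r}: "
                f"need {n}, have {len(pool)}"
            )
        pick = rng.choice(pool, size=n, replace=False)
        chosen.extend(pick.tolist())
        provenance[t] = tuple(ids[i] for i in pick)
    spec.selected_cells = provenance
    expr = pd.Series(X[chosen].sum(axis=0), index=corpus.genes, name=spec.mixture_id)
    universe = list(label_universe) if label_universe is not None else list(spec.counts)
    return expr, spec.truth_row(universe)


def assemble_set(
    corpus: AnnotatedCorpus,
    specs: list[MixtureSpec],
    *,
    level: str | Mapping[str, str] = "major",
    label_universe: Sequence[str] | None = None,
    metadata: dict | None = None,
) -> PseudobulkSet:
    """Assemble expression + truth for a list of planned mixtures."""
    if label_universe is None:
        label_universe = sorted({t for s in specs for t in s.counts})
    labels = resolve_labels(corpus, level).to_numpy()
    patients = corpus.obs["patient"].to_numpy()
    pools: dict[tuple[str, str], np.ndarray] = {}
    for s in specs:
        for t in s.counts:
            key = (s.donor, t)
            if key not in pools:
                pools[key] = np.flatnonzero((patients == s.donor) & (labels == t))
    X = corpus.X
    expr_rows, truth_rows = [], []
    for s in specs:
        rng = np.random.default_rng(s.seed)
        e, t = assemble_mixture(
            corpus, s, rng, level=level, label_universe=label_universe,
            _pools=pools, _X=X,
        )
        expr_rows.append(e)
        truth_rows.append(t)
    expression = pd.DataFrame(expr_rows)
    truth = pd.DataFrame(truth_rows)
    return PseudobulkSet(
        expression=expression,
        truth=truth,
        specs=specs,
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# the three designs
# ---------------------------------------------------------------------------

def simulate_training_set(
    corpus: AnnotatedCorpus,
    donors: Sequence[str],
    per_donor: int = 5000,
    level: str | Mapping[str, str] = "major",
    seed: int = 0,
    *,
    assemble: bool = True,
) -> PseudobulkSet:
    """Sparse mixtures with no fixed label (the training design).

    The benchmark's full scale is 5000 mixtures per donor (90,000 across 18
    training patients); the counts follow directly from the plan.
    """
    donor_types = donor_available_types(corpus, level, donors)
    specs = plan_mixtures(donor_types, list(donors), per_donor, seed, id_prefix="train")
    meta = {"design": "training", "level": level, "seed": seed, "per_donor": per_donor}
    if not assemble:
        universe = sorted({t for ts in donor_types.values() for t in ts})
        truth = pd.DataFrame([s.truth_row(universe) for s in specs])
        return PseudobulkSet(expression=None, truth=truth, specs=specs, metadata=meta)
    return assemble_set(corpus, specs, level=level, metadata=meta)


def simulate_purity_series(
    corpus: AnnotatedCorpus,
    donors: Sequence[str],
    purity_grid: Sequence[float] = DEFAULT_PURITY_GRID,
    per_donor_per_level: int = 250,
    level: str | Mapping[str, str] = "major",
    seed: int = 0,
    *,
    cancer_label: str = CANCER_LABEL,
    assemble: bool = True,
) -> PseudobulkSet:
    """Fixed-tumour-purity test mixtures over a purity grid.

    At the benchmark's scale (8 test donors x 19 levels x 250) this yields
    38,000 mixtures.  The cancer fraction of every mixture equals its grid
    value exactly; on the default grid purity*500 is integral, so the
    recorded truth matches the nominal purity bit-for-bit.
    """
    donor_types = donor_available_types(corpus, level, donors)
    specs = plan_purity_series(
        donor_types, donors, purity_grid, per_donor_per_level, seed, cancer_label
    )
    meta = {
        "design": "purity_series", "level": level, "seed": seed,
        "purity_grid": [float(p) for p in purity_grid],
    }
    if not assemble:
        universe = sorted({t for ts in donor_types.values() for t in ts})
        truth = pd.DataFrame([s.truth_row(universe) for s in specs])
        return PseudobulkSet(expression=None, truth=truth, specs=specs, metadata=meta)
    return assemble_set(corpus, specs, level=level, metadata=meta)


def simulate_lineage_set(
    corpus: AnnotatedCorpus,
    donors: Sequence[str],
    level_config: Mapping[str, str],
    per_donor: int = 250,
    fixed_purity: float | None = None,
    exclude_types: set[str] | None = None,
    seed: int = 0,
    *,
    cancer_label: str = CANCER_LABEL,
    assemble: bool = True,
) -> PseudobulkSet:
    """Lineage-granular mixtures (normal-epithelial or immune designs).

    ``level_config`` maps each major label to the level its labels are taken
    from (majors not named stay at major resolution).  ``exclude_types``
    removes labels from the available pool before drawing — e.g. the
    normal-epithelial children for the "all excluded" arm.  ``fixed_purity``
    pins the cancer fraction (the benchmark uses 50%).
    """
    donor_types = donor_available_types(corpus, level_config, donors)
    requested_children = {
        lbl
        for major, lvl in level_config.items()
        if lvl != "major"
        for lbl in resolve_labels(corpus, level_config)[
            corpus.obs["major"].astype(str) == major
        ].unique()
    }
    all_available = {t for ts in donor_types.values() for t in ts}
    ghost = requested_children - all_available
    if ghost:
        raise ValueError(f"requested child labels absent in every donor: {sorted(ghost)}")
    if exclude_types:
        donor_types = {
            d: [t for t in ts if t not in exclude_types] for d, ts in donor_types.items()
        }
    specs = plan_mixtures(
        donor_types, list(donors), per_donor, seed,
        fixed_label=cancer_label if fixed_purity is not None else None,
        fixed_fraction=fixed_purity,
        id_prefix="lin",
    )
    meta = {
        "design": "lineage", "level": dict(level_config), "seed": seed,
        "fixed_purity": fixed_purity,
        "exclude_types": sorted(exclude_types) if exclude_types else [],
    }
    if not assemble:
        universe = sorted({t for ts in donor_types.values() for t in ts})
        truth = pd.DataFrame([s.truth_row(universe) for s in specs])
        return PseudobulkSet(expression=None, truth=truth, specs=specs, metadata=meta)
    return assemble_set(corpus, specs, level=level_config, metadata=meta)
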