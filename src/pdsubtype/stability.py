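"""Robustness of the subtypes to patient subsampling and to adding a view.

Patient-based stability: repeatedly drop a fraction of patients, re-run
the full fusion/clustering search on the subset, and match the subset
clusters to the reference clustering with the Kuhn-Munkres (Hungarian)
optimal assignment; stability is the fraction of shared patients whose
matched label agrees.  View-based sensitivity: add a further (e.g.
biomarker) kernel and re-run the search optimising the Rand index against
the reference clustering instead of the silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, rand_score

from .cohort_io import CohortTable
from .cluster_pipeline import SearchResult, joint_search

__all__ = [
    "StabilityReport",
    "SensitivityReport",
    "hungarian_match",
    "rand_index",
    "adjusted_rand_index",
    "subsample_stability",
    "add_view_sensitivity",
]


@dataclass
class SubsetOutcome:
    removed_ids: list
    agreement: float | None
    confusion: pd.DataFrame | None
    mapping: dict | None
    error: str | None = None


@dataclass
class StabilityReport:
    per_subset: list[SubsetOutcome]
    mean_agreement: float
    n_subsets: int
    tunes_per_subset: int
    misassignment_counts: pd.Series | None = None

    def to_text(self) -> str:
        lines = [
            f"n_subsets: {self.n_subsets}",
            f"tunes_per_subset: {self.tunes_per_subset}",
            f"mean_agreement: {self.mean_agreement:.4f}",
        ]
        for i, sub in enumerate(self.per_subset, 1):
            if sub.error:
                lines.append(f"subset {i}: failed ({sub.error})")
            else:
                lines.append(f"subset {i}: agreement {sub.agreement:.4f}")
        return "\n".join(lines) + "\n"


@dataclass
class SensitivityReport:
    baseline_labels: pd.Series
    extended_labels: pd.Series
    rand_index: float
    adjusted_rand_index: float
    weights: np.ndarray
    view_names: list[str]
    rounds: int
    search: SearchResult | None = None


def _as_series(labels, index=None) -> pd.Series:
    if isinstance(labels, pd.Series):
        return labels
    if index is None:
        index = pd.RangeIndex(len(labels))
    return pd.Series(np.asarray(labels), index=index)


def hungarian_match(reference, candidate) -> tuple[dict, float]:
    """Optimal label matching between a reference and a subset clustering.

    Both arguments are label series indexed by patient id (plain arrays are
    matched positionally).  The cluster-overlap contingency table on the
    shared patients is maximised over label bijections by the Hungarian
    algorithm; ``agreement`` is matched overlap divided by the number of
    shared patients.  With unequal cluster counts the assignment is
    rectangular and unmatched clusters contribute nothing.
    """
    ref = _as_series(reference)
    cand = _as_series(candidate, index=ref.index[: len(candidate)] if not isinstance(candidate, pd.Series) else None)
    shared = ref.index.intersection(cand.index)
    if len(shared) == 0:
        raise ValueError("reference and candidate share no patients")
    table = pd.crosstab(cand.loc[shared], ref.loc[shared])
    rows, cols = linear_sum_assignment(table.to_numpy(), maximize=True)
    mapping = {table.index[i]: table.columns[j] for i, j in zip(rows, cols)}
    matched = int(table.to_numpy()[rows, cols].sum())
    return mapping, matched / len(shared)


def rand_index(a, b) -> float:
    """Unadjusted Rand index: fraction of concordant patient pairs."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    return float(rand_score(a, b))


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected Rand index (zero expected under random labels)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    return float(adjusted_rand_score(a, b))


def _subset_cohort(cohort: CohortTable, keep: pd.Index) -> CohortTable:
    return CohortTable(
        data=cohort.data.loc[keep].copy(),
        view_spec=cohort.view_spec,
        proteins=None if cohort.proteins is None else cohort.proteins.loc[keep].copy(),
    )


def subsample_stability(
    cohort: CohortTable,
    reference_labels,
    n_subsets: int = 10,
    drop_fraction: float = 0.10,
    tunes_per_subset: int = 100,
    seed: int = 0,
    k_range=None,
    views: tuple[str, ...] = ("motor", "non-motor"),
) -> StabilityReport:
    """Patient-deletion stability of a reference clustering.

    For each of ``n_subsets`` seeded draws, ``drop_fraction`` of the
    patients is removed (without replacement), the joint hyperparameter
    search is re-run from scratch on the subset, and the resulting clusters
    are matched to the reference with the Hungarian algorithm.  Per-subset
    failures are recorded, not fatal; only all-subsets-failed raises.
    """
    from .cluster_pipeline import DEFAULT_K_RANGE

    ref = _as_series(reference_labels, index=cohort.patient_ids)
    rng = np.random.default_rng(seed)
    k_range = DEFAULT_K_RANGE if k_range is None else k_range
    n_drop = int(round(drop_fraction * cohort.n))
    outcomes: list[SubsetOutcome] = []
    mis_counts: dict = {}
    for _ in range(n_subsets):
        removed = rng.choice(cohort.patient_ids, size=n_drop, replace=False)
        keep = cohort.patient_ids.difference(pd.Index(removed), sort=False)
        sub = _subset_cohort(cohort, keep)
        child_seed = int(rng.integers(0, 2**31 - 1))
        try:
            result = joint_search(
                sub, k_range=tuple(k_range), n_trials=tunes_per_subset,
                seed=child_seed, views=views,
            )
        except (RuntimeError, ValueError) as exc:
            outcomes.append(SubsetOutcome(list(removed), None, None, None, str(exc)))
            continue
        cand = pd.Series(result.best.labels, index=keep)
        mapping, agreement = hungarian_match(ref, cand)
        mapped = cand.map(lambda lab: mapping.get(lab, -1))
        confusion = pd.crosstab(ref.loc[keep], mapped)
        for pid in keep:
            if mapped.loc[pid] != ref.loc[pid]:
                key = (ref.loc[pid], mapped.loc[pid])
                mis_counts[key] = mis_counts.get(key, 0) + 1
        outcomes.append(SubsetOutcome(list(removed), agreement, confusion, mapping))
    agreements = [o.agreement for o in outcomes if o.agreement is not None]
    if not agreements:
        raise RuntimeError("all stability subsets failed")
    mis = (
        pd.Series(mis_counts).sort_values(ascending=False)
        if mis_counts
        else pd.Series(dtype=int)
    )
    return StabilityReport(
        per_subset=outcomes,
        mean_agreement=float(np.mean(agreements)),
        n_subsets=n_subsets,
        tunes_per_subset=tunes_per_subset,
        misassignment_counts=mis,
    )


def add_view_sensitivity(
    cohort: CohortTable,
    extra_view: str,
    reference_labels,
    rounds: int = 50,
    seed: int = 0,
    base_views: tuple[str, ...] = ("motor", "non-motor"),
    k_range=None,
) -> SensitivityReport:
    """Effect of adding a data view on the clustering.

    Re-runs the hyperparameter search with the extra view's kernel included,
    optimising the (unadjusted) Rand index between the extended clustering
    and the reference labels for ``rounds`` trials.  Reports the best Rand
    index, the extended labels and the learned weights over all views; the
    adjusted Rand index is reported alongside, clearly labelled.
    """
    from .cluster_pipeline import DEFAULT_K_RANGE

    ref = _as_series(reference_labels, index=cohort.patient_ids)
    views = tuple(base_views) + (extra_view,)
    k_range = DEFAULT_K_RANGE if k_range is None else k_range

    def objective(clustering, fusion):
        return rand_index(ref.to_numpy(), clustering.labels)

    result = joint_search(
        cohort, k_range=tuple(k_range), n_trials=rounds, seed=seed,
        views=views, objective=objective,
    )
    ext = pd.Series(result.best.labels, index=cohort.patient_ids)
    return SensitivityReport(
        baseline_labels=ref,
        extended_labels=ext,
        rand_index=rand_index(ref.to_numpy(), ext.to_numpy()),
        adjusted_rand_index=adjusted_rand_index(ref.to_numpy(), ext.to_numpy()),
        weights=result.best_fusion.weights,
        view_names=list(views),
        rounds=rounds,
        search=result,
    )
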