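"""Cohort table loading, cleaning and per-view normalisation.

A cohort is a patient-by-variable table whose columns are assigned to
clinical *views* (motor, non-motor, and optionally biomarker) plus
covariates and categorical descriptors.  Cleaning follows the usual
cross-sectional protocol: complete-case filtering on the clustering views,
explicit mean imputation of designated columns only (never silently), and
per-view z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ViewSpec",
    "CohortTable",
    "CleaningReport",
    "load_cohort",
    "complete_case_filter",
    "mean_impute",
    "zscore_view",
]

MISSING_TOKENS = {"", "na", "nan"}

VIEW_NAMES = ("motor", "non-motor", "biomarker")


class CohortConfigError(ValueError):
    """A view specification and a data file disagree."""


@dataclass
class ViewSpec:
    """Assignment of cohort columns to clinical views.

    ``motor`` and ``non-motor`` are the clustering views and must be
    non-empty; ``biomarker`` is optional.  View column sets must be
    pairwise disjoint.
    """

    motor: list[str]
    non_motor: list[str]
    biomarker: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    categorical: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.motor or not self.non_motor:
            raise CohortConfigError("motor and non-motor views must be non-empty")
        seen: set[str] = set()
        for cols in (self.motor, self.non_motor, self.biomarker):
            overlap = seen & set(cols)
            if overlap:
                raise CohortConfigError(f"columns assigned to multiple views: {sorted(overlap)}")
            seen |= set(cols)

    def view_columns(self, view: str) -> list[str]:
        if view == "motor":
            return list(self.motor)
        if view == "non-motor":
            return list(self.non_motor)
        if view == "biomarker":
            return list(self.biomarker)
        raise KeyError(f"unknown view {view!r}; expected one of {VIEW_NAMES}")

    @property
    def numeric_columns(self) -> list[str]:
        return self.motor + self.non_motor + self.biomarker + self.covariates

    @property
    def all_columns(self) -> list[str]:
        return self.numeric_columns + self.categorical


@dataclass
class CohortTable:
    """Patient-by-variable table with a view assignment.

    ``data`` is indexed by unique patient id; numeric missingness is
    represented by NaN, so the missing mask is derived, never stored
    separately.  ``proteins`` optionally carries a patient-by-protein
    quantification matrix aligned on the same index.
    """

    data: pd.DataFrame
    view_spec: ViewSpec
    proteins: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient ids: {dup}")
        missing = [c for c in self.view_spec.all_columns if c not in self.data.columns]
        if missing:
            raise CohortConfigError(f"cohort table lacks required columns: {missing}")
        if self.proteins is not None and not self.proteins.index.equals(self.data.index):
            raise ValueError("protein matrix index must match the cohort patient ids")

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data[self.view_spec.numeric_columns].isna()

    def view_matrix(self, view: str) -> pd.DataFrame:
        return self.data[self.view_spec.view_columns(view)]


@dataclass
class CleaningReport:
    n_input: int
    n_retained: int
    n_dropped_complete_case: int
    imputed_cells: list[tuple[object, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + self.n_dropped_complete_case:
            raise ValueError("cleaning report counts do not reconcile")

    def to_text(self) -> str:
        lines = [
            f"n_input: {self.n_input}",
            f"n_retained: {self.n_retained}",
            f"n_dropped_complete_case: {self.n_dropped_complete_case}",
            f"n_imputed_cells: {len(self.imputed_cells)}",
        ]
        for pid, col in self.imputed_cells:
            lines.append(f"imputed: {pid} {col}")
        return "\n".join(lines) + "\n"


def _coerce_numeric(series: pd.Series) -> pd.Series:
    # Accept common missing tokens case-insensitively; any other
    # unparseable cell also becomes missing.
    cleaned = series.map(
        lambda v: np.nan
        if (isinstance(v, str) and v.strip().lower() in MISSING_TOKENS)
        else v
    )
    return pd.to_numeric(cleaned, errors="coerce")


def load_cohort(
    path: str | Path,
    view_spec: ViewSpec,
    sep: str = ",",
    id_column: str = "patient_id",
) -> CohortTable:
    """Read a delimited cohort file and type its columns per the view spec.

    Numeric cells that fail to parse (including the tokens "", "NA",
    "NaN" case-insensitively) become missing values.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise CohortConfigError(f"missing required column: {id_column}")
    for col in view_spec.all_columns:
        if col not in df.columns:
            raise CohortConfigError(f"missing required column: {col}")
    df = df.set_index(id_column)
    for col in view_spec.numeric_columns:
        df[col] = _coerce_numeric(df[col])
    for col in view_spec.categorical:
        df[col] = df[col].map(
            lambda v: np.nan if str(v).strip().lower() in MISSING_TOKENS else v
        )
    return CohortTable(data=df, view_spec=view_spec)


def save_cohort(cohort: CohortTable, path: str | Path, sep: str = ",") -> None:
    cohort.data.to_csv(path, sep=sep, index_label="patient_id")


def complete_case_filter(
    cohort: CohortTable, views: tuple[str, ...] = ("motor", "non-motor")
) -> tuple[CohortTable, CleaningReport]:
    """Retain exactly the patients with no missing value in the named views."""
    for v in views:
        if v not in ("motor", "non-motor"):
            raise ValueError("complete-case filtering applies to the clustering views only")
    cols: list[str] = []
    for v in views:
        cols += cohort.view_spec.view_columns(v)
    keep = ~cohort.data[cols].isna().any(axis=1)
    n_input = cohort.n
    n_retained = int(keep.sum())
    if n_retained == 0:
        raise ValueError("no complete cases remain after filtering")
    filtered = CohortTable(
        data=cohort.data.loc[keep].copy(),
        view_spec=cohort.view_spec,
        proteins=None if cohort.proteins is None else cohort.proteins.loc[keep].copy(),
    )
    report = CleaningReport(
        n_input=n_input,
        n_retained=n_retained,
        n_dropped_complete_case=n_input - n_retained,
    )
    return filtered, report


def mean_impute(cohort: CohortTable, columns: list[str]) -> tuple[CohortTable, list[tuple[object, str]]]:
    """Replace missing cells in the named numeric columns by the column mean.

    Imputation is never applied outside the explicit column list.  Returns
    the imputed table and the list of (patient id, column) cells filled.
    """
    data = cohort.data.copy()
    imputed: list[tuple[object, str]] = []
    for col in columns:
        if col not in data.columns:
            raise KeyError(f"unknown column {col!r}")
        series = data[col]
        if series.isna().all():
            raise ValueError(f"column {col!r} is entirely missing; mean undefined")
        mask = series.isna()
        if mask.any():
            data.loc[mask, col] = float(series.mean())
            imputed += [(pid, col) for pid in data.index[mask]]
    return CohortTable(data=data, view_spec=cohort.view_spec, proteins=cohort.proteins), imputed


def zscore_view(cohort: CohortTable, view: str, ddof: int = 1) -> np.ndarray:
    """Z-score the columns of one view; returns an N x p float matrix.

    Requires the view to be complete (run the complete-case filter and any
    imputation first).  ``ddof=1`` uses the sample standard deviation;
    ``ddof=0`` the population convention — the choice is immaterial
    downstream because kernel bandwidths are median-distance scaled.
    """
    cols = cohort.view_spec.view_columns(view)
    M = cohort.data[cols]
    if M.isna().any().any():
        bad = M.columns[M.isna().any()].tolist()
        raise ValueError(f"view {view!r} has missing values in {bad}; filter or impute first")
    X = M.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        const = [cols[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant column(s) cannot be z-scored: {const}")
    return (X - X.mean(axis=0)) / sd
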