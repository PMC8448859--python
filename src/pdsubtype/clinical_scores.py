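"""Derived MDS-UPDRS motor phenotype scores and classifications.

The tremor score is the mean of 11 MDS-UPDRS tremor items and the PIGD
(postural instability / gait difficulty) score the mean of 5 items, each
item scored 0-4.  The tremor/PIGD ratio assigns the motor phenotype:
tremor-dominant (TD) at ratio >= 1.15, PIGD at ratio <= 0.90, indeterminate
between.  Patients classified TD (or PIGD) off medication whose class
changes on medication are "shifters"; patients indeterminate off medication
form their own category.  RBD positivity is a threshold on the 0-13 RBD
screening questionnaire total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_io import CohortTable

__all__ = [
    "tremor_score",
    "pigd_score",
    "classify_motor_phenotype",
    "shifter_status",
    "rbd_positive",
    "append_phenotypes",
]

N_TREMOR_ITEMS = 11
N_PIGD_ITEMS = 5
TD_RATIO = 1.15
PIGD_RATIO = 0.90


def _mean_items(items, n_required: int, what: str) -> float:
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != n_required:
        raise ValueError(f"expected exactly {n_required} {what} items, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 4):
        raise ValueError(f"{what} items must lie in [0, 4]")
    return float(arr.mean())


def tremor_score(items) -> float:
    """Mean of the 11 MDS-UPDRS tremor items (each 0-4)."""
    return _mean_items(items, N_TREMOR_ITEMS, "tremor")


def pigd_score(items) -> float:
    """Mean of the 5 MDS-UPDRS postural-instability/gait items (each 0-4)."""
    return _mean_items(items, N_PIGD_ITEMS, "PIGD")


def classify_motor_phenotype(tremor: float, pigd: float) -> str:
    """TD / indeterminate / PIGD from the tremor-to-PIGD score ratio.

    Boundary-inclusive: ratio >= 1.15 is TD, ratio <= 0.90 is PIGD.  A zero
    PIGD score with positive tremor is TD, zero tremor with positive PIGD
    is PIGD, and both-zero is indeterminate.
    """
    if tremor < 0 or pigd < 0:
        raise ValueError("phenotype scores must be non-negative")
    if pigd == 0.0:
        return "TD" if tremor > 0 else "indeterminate"
    if tremor == 0.0:
        return "PIGD"
    ratio = tremor / pigd
    if ratio >= TD_RATIO:
        return "TD"
    if ratio <= PIGD_RATIO:
        return "PIGD"
    return "indeterminate"


def shifter_status(off_class: str, on_class: str) -> str:
    """Medication-state phenotype shift category.

    TD off-state changing class on medication -> "TD-shifter"; PIGD
    off-state changing class -> "PIGD-shifter"; indeterminate off-state is
    its own category regardless of the on-state; otherwise "non-shifter".
    """
    valid = {"TD", "PIGD", "indeterminate"}
    if off_class not in valid or on_class not in valid:
        raise ValueError(f"classes must be in {sorted(valid)}")
    if off_class == "indeterminate":
        return "indeterminate-off"
    if off_class != on_class:
        return f"{off_class}-shifter"
    return "non-shifter"


def rbd_positive(rbdsq: float, threshold: int = 5) -> bool:
    """RBD-positive phenotype: questionnaire total at or above threshold."""
    if not 0 <= rbdsq <= 13:
        raise ValueError("RBDSQ total must lie in [0, 13]")
    return rbdsq >= threshold


def append_phenotypes(
    cohort: CohortTable,
    rbd_threshold: int = 5,
    item_prefixes: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Append derived phenotype columns for each medication state.

    ``item_prefixes`` maps medication state ("on"/"off") to the column
    prefixes of the tremor and PIGD item blocks (defaults to
    ``tremor_on``/``pigd_on`` etc. as emitted by the synthetic generator).
    Returns a copy of the cohort data with ``tremor_score_<state>``,
    ``pigd_score_<state>``, ``motor_phenotype_<state>``, ``shifter_status``
    and ``rbd_phenotype`` columns appended.
    """
    if item_prefixes is None:
        item_prefixes = {"on": ("tremor_on", "pigd_on"), "off": ("tremor_off", "pigd_off")}
    data = cohort.data.copy()
    classes: dict[str, pd.Series] = {}
    for state, (tremor_prefix, pigd_prefix) in item_prefixes.items():
        tcols = sorted(c for c in data.columns if c.startswith(tremor_prefix + "_"))
        pcols = sorted(c for c in data.columns if c.startswith(pigd_prefix + "_"))
        tscores = data[tcols].apply(lambda row: tremor_score(row.to_numpy()), axis=1)
        pscores = data[pcols].apply(lambda row: pigd_score(row.to_numpy()), axis=1)
        data[f"tremor_score_{state}"] = tscores
        data[f"pigd_score_{state}"] = pscores
        classes[state] = pd.Series(
            [classify_motor_phenotype(t, p) for t, p in zip(tscores, pscores)],
            index=data.index,
        )
        data[f"motor_phenotype_{state}"] = classes[state]
    if {"on", "off"} <= set(classes):
        data["shifter_status"] = [
            shifter_status(off, on) for off, on in zip(classes["off"], classes["on"])
        ]
    if "rbdsq" in data.columns:
        data["rbd_phenotype"] = [
            "positive" if rbd_positive(v, rbd_threshold) else "negative"
            for v in data["rbdsq"]
        ]
    return data
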