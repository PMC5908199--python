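"""Derived per-subject scores.

The central quantity is the Fc polyfunctionality Z-score: each effector
function's scores are standardized across the cohort (mean 0, SD 1) and
the four standardized values are summed per subject, so all four
functions contribute equitably regardless of their native units.

Also here: the IgG subclass diversity score (IgG2 + IgG4)/IgG1, relative
subclass abundances, the activating/inhibitory receptor binding ratio
FcγRIIa/FcγRIIb, and confusion-matrix classification metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError, MissingDataError

SUBCLASSES = ("IgG1", "IgG2", "IgG3", "IgG4")


@dataclass(frozen=True)
class SubclassProfile:
    """Background-corrected antigen-specific IgG subclass MFIs."""

    subject_id: str
    antigen: str
    igg_total: float
    igg1: float
    igg2: float
    igg3: float
    igg4: float

    def __post_init__(self) -> None:
        for name in ("igg_total", "igg1", "igg2", "igg3", "igg4"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative after background correction")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with the bNAb group as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InputError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def zscore_standardize(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, ddof=1); order preserved."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InputError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("cannot Z-score a constant vector")
    return (x - x.mean()) / sd


def polyfunctionality(z_matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum per-function Z-scores into a per-subject polyfunctionality score.

    ``z_matrix`` is subjects x functions of already-standardized values;
    any missing cell is an error — no imputation is performed.
    """
    if z_matrix.isna().any().any():
        bad = z_matrix.index[z_matrix.isna().any(axis=1)].tolist()
        raise MissingDataError(f"missing function values for subjects {bad}")
    out = z_matrix.copy()
    out["total_z"] = z_matrix.sum(axis=1)
    return out


def polyfunctionality_from_scores(scores: pd.DataFrame,
                                  value_col: str = "score") -> pd.DataFrame:
    """Standardize each function across subjects, then sum per subject.

    ``scores`` is long format with subject_id / function / ``value_col``
    columns (one antigen, one timepoint).  Returns a subjects x functions
    Z-score table with a ``total_z`` column.
    """
    wide = scores.pivot_table(index="subject_id", columns="function",
                              values=value_col, aggfunc="mean")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise MissingDataError(f"missing function scores for subjects {bad}")
    z = wide.apply(lambda col: zscore_standardize(col.to_numpy()), axis=0,
                   result_type="broadcast")
    return polyfunctionality(z)


def subclass_diversity_score(profile: SubclassProfile) -> float:
    """(IgG2 + IgG4) / IgG1 — higher values mean broader class switching."""
    if profile.igg1 == 0:
        raise DegenerateInputError("IgG1 MFI is zero; diversity score undefined")
    return (profile.igg2 + profile.igg4) / profile.igg1


def relative_subclass_abundance(profile: SubclassProfile,
                                mode: str = "to_igg1") -> dict[str, float]:
    """Subclass MFIs as ratios to IgG1 or to total antigen-specific IgG."""
    if mode == "to_igg1":
        if profile.igg1 == 0:
            raise DegenerateInputError("IgG1 MFI is zero")
        return {
            "IgG2": profile.igg2 / profile.igg1,
            "IgG3": profile.igg3 / profile.igg1,
            "IgG4": profile.igg4 / profile.igg1,
        }
    if mode == "to_total":
        if profile.igg_total == 0:
            raise DegenerateInputError("total IgG MFI is zero")
        return {
            "IgG1": profile.igg1 / profile.igg_total,
            "IgG2": profile.igg2 / profile.igg_total,
            "IgG3": profile.igg3 / profile.igg_total,
            "IgG4": profile.igg4 / profile.igg_total,
        }
    raise InputError(f"unknown mode {mode!r}; use 'to_igg1' or 'to_total'")


def activating_inhibitory_ratio(fcgr2a_mfi: float, fcgr2b_mfi: float) -> float:
    """Activating FcγRIIa over inhibitory FcγRIIb binding MFI."""
    if fcgr2a_mfi < 0 or fcgr2b_mfi < 0:
        raise InputError("binding MFIs must be non-negative")
    if fcgr2b_mfi == 0:
        raise DegenerateInputError("FcγRIIb MFI is zero; ratio undefined")
    return fcgr2a_mfi / fcgr2b_mfi


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Sensitivity, specificity and accuracy (as percentages) from a 2x2 table.

    bNAb is the positive class: sensitivity = TP/(TP+FN) is the fraction
    of observed bNAb developers correctly identified.
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise DegenerateInputError("a confusion-matrix margin is zero")
    return {
        "sensitivity": 100.0 * cm.tp / (cm.tp + cm.fn),
        "specificity": 100.0 * cm.tn / (cm.tn + cm.fp),
        "accuracy": 100.0 * (cm.tp + cm.tn) / cm.n,
    }
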