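"""Per-assay composite scores from raw Fc effector readouts.

Each of the four Fc effector functions has its own readout convention:

* ADCP (phagocytosis) — a phagocytic score, the geometric MFI of
  antigen-coated beads multiplied by the percentage bead uptake.
* ADCD (complement deposition) — geometric MFI multiplied by the
  percentage of target cells positive for C3b deposition.
* ADCC (cytotoxicity) — % granzyme-B-positive target cells after
  subtracting the no-IgG background wells.
* ADCT (trogocytosis) — double-positive (membrane-dye + CFSE) monocytes
  as a percentage of total monocytes.

On top of the per-well scores this module implements the negative-control
threshold (mean + 3 SD of HIV-negative samples, subtracted and floored at
zero) and HIVIG-based plate normalization.

Percentages are carried on the 0-100 scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

FUNCTIONS = ("ADCP", "ADCC", "ADCD", "ADCT")


@dataclass(frozen=True)
class RawAssayMeasurement:
    """One subject x antigen x function readout.

    ``background_percent`` is only meaningful for ADCC (no-IgG wells); it
    is carried as 0 for the other functions.
    """

    subject_id: str
    antigen: str
    function: str
    percent_positive: float
    mfi: float
    background_percent: float = 0.0
    timepoint_months: int = 6

    def __post_init__(self) -> None:
        if self.function not in FUNCTIONS:
            raise InputError(f"unknown Fc function {self.function!r}")
        if not 0.0 <= self.percent_positive <= 100.0:
            raise InputError("percent_positive must be in [0, 100]")
        if self.mfi < 0:
            raise InputError("mfi must be non-negative")
        if not 0.0 <= self.background_percent <= 100.0:
            raise InputError("background_percent must be in [0, 100]")


@dataclass(frozen=True)
class AssayScore:
    """A per-well composite score.

    Units are %xMFI for ADCP/ADCD and % for ADCC/ADCT.
    ``above_negative_threshold`` is set by :func:`apply_threshold`.
    """

    subject_id: str
    antigen: str
    function: str
    score: float
    above_negative_threshold: bool = True
    timepoint_months: int = 6


def adcp_score(percent_bead_uptake: float, geometric_mfi: float) -> float:
    """Phagocytic score: geometric bead MFI x % bead uptake (0-100 scale)."""
    if percent_bead_uptake < 0 or geometric_mfi < 0:
        raise InputError("ADCP inputs must be non-negative")
    if percent_bead_uptake > 100:
        raise InputError("percent bead uptake must be <= 100")
    return geometric_mfi * percent_bead_uptake


def adcd_score(percent_c3b_positive: float, geometric_mfi: float) -> float:
    """Complement deposition score: geometric MFI x % C3b-positive cells."""
    if percent_c3b_positive < 0 or geometric_mfi < 0:
        raise InputError("ADCD inputs must be non-negative")
    if percent_c3b_positive > 100:
        raise InputError("percent C3b positive must be <= 100")
    return geometric_mfi * percent_c3b_positive


def adcc_activity(percent_gzb: float, background_percent: float) -> float:
    """% granzyme B activity net of the no-IgG background, floored at 0."""
    for v in (percent_gzb, background_percent):
        if not 0.0 <= v <= 100.0:
            raise InputError("ADCC percentages must be in [0, 100]")
    return max(percent_gzb - background_percent, 0.0)


def adct_fraction(double_positive_thp1: int, total_thp1: int) -> float:
    """Trogocytosis: double-positive THP-1 cells as % of total THP-1 cells."""
    if total_thp1 <= 0:
        raise InputError("total THP-1 count must be positive")
    if not 0 <= double_positive_thp1 <= total_thp1:
        raise InputError("double-positive count must be in [0, total]")
    return 100.0 * double_positive_thp1 / total_thp1


def negative_threshold(control_values: Sequence[float]) -> float:
    """Mean + 3 x sample SD of HIV-negative control readouts.

    This is the positivity threshold subtracted from HIV-positive data
    before multivariate analysis.
    """
    values = np.asarray(control_values, dtype=float)
    if values.size < 2:
        raise InputError("need at least 2 control values to estimate an SD")
    return float(values.mean() + 3.0 * values.std(ddof=1))


def apply_threshold(
    scores: Sequence[AssayScore], threshold: float
) -> list[AssayScore]:
    """Subtract ``threshold`` from each score, flooring at zero.

    ``above_negative_threshold`` records whether the original score
    exceeded the threshold (strictly).
    """
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    out = []
    for s in scores:
        out.append(
            replace(
                s,
                score=max(s.score - threshold, 0.0),
                above_negative_threshold=s.score > threshold,
            )
        )
    return out


def plate_normalize(
    scores: Sequence[float],
    plates: Sequence[str],
    reference_scores_by_plate: Mapping[str, float],
) -> np.ndarray:
    """Normalize scores across plates using a per-plate HIVIG reference.

    Each score is divided by its plate's reference score and rescaled by
    the grand mean of the references, so the reference itself maps to the
    same value on every plate and a single-plate run is left unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    if len(plates) != scores.size:
        raise InputError("scores and plates must have equal length")
    refs = {}
    for p in set(plates):
        if p not in reference_scores_by_plate:
            raise ConfigurationError(f"no reference (HIVIG) score for plate {p!r}")
        r = float(reference_scores_by_plate[p])
        if r <= 0:
            raise ConfigurationError(f"reference score for plate {p!r} must be > 0")
        refs[p] = r
    grand = float(np.mean([refs[p] for p in set(plates)]))
    factors = np.array([grand / refs[p] for p in plates])
    return scores * factors


def score_measurement(m: RawAssayMeasurement) -> AssayScore:
    """Dispatch one raw readout to its function's scoring rule."""
    if m.function == "ADCP":
        s = adcp_score(m.percent_positive, m.mfi)
    elif m.function == "ADCD":
        s = adcd_score(m.percent_positive, m.mfi)
    elif m.function == "ADCC":
        s = adcc_activity(m.percent_positive, m.background_percent)
    else:  # ADCT
        s = m.percent_positive
    return AssayScore(m.subject_id, m.antigen, m.function, s,
                      timepoint_months=m.timepoint_months)


def score_table(raw: pd.DataFrame, controls: pd.DataFrame | None = None) -> pd.DataFrame:
    """Score a long-format raw table and apply negative-control thresholds.

    ``raw`` needs columns subject_id, antigen, function, percent_positive,
    mfi, background_percent, timepoint_months.  ``controls`` (same layout,
    HIV-negative donors) defines a mean + 3 SD threshold per
    antigen x function pair; when omitted no thresholding is applied.
    """
    required = {"subject_id", "antigen", "function", "percent_positive",
                "mfi", "background_percent", "timepoint_months"}
    missing = required - set(raw.columns)
    if missing:
        raise InputError(f"raw table missing columns: {sorted(missing)}")

    def _score_rows(df: pd.DataFrame) -> pd.Series:
        return df.apply(
            lambda r: score_measurement(
                RawAssayMeasurement(
                    str(r.subject_id), str(r.antigen), str(r.function),
                    float(r.percent_positive), float(r.mfi),
                    float(r.background_percent), int(r.timepoint_months),
                )
            ).score,
            axis=1,
        )

    out = raw.copy()
    out["score"] = _score_rows(raw) if len(raw) else []
    out["above_negative_threshold"] = True
    if controls is not None and len(controls):
        ctrl = controls.copy()
        ctrl["score"] = _score_rows(ctrl)
        for (ag, fn), grp in ctrl.groupby(["antigen", "function"]):
            if len(grp) < 2:
                continue
            thr = negative_threshold(grp["score"].to_numpy())
            sel = (out["antigen"] == ag) & (out["function"] == fn)
            above = out.loc[sel, "score"] > thr
            out.loc[sel, "score"] = (out.loc[sel, "score"] - thr).clip(lower=0.0)
            out.loc[sel, "above_negative_threshold"] = above
    return out
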