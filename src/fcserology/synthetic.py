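"""Synthetic cohorts and sequence sets for the Fc effector pipeline.

The generator emulates a two-group acute-HIV-infection cohort — subjects
who go on to develop broadly neutralizing antibodies (bNAb) versus those
who do not — sampled at a single post-infection timepoint, plus
HIV-negative control donors.  Feature families mirror what the analysis
consumes: raw (% positive, MFI) readouts for the four Fc effector
functions against each antigen, antigen-specific Fcγ-receptor/C1q
binding MFIs, IgG subclass MFIs, and clinical covariates (CXCL13, AID
MFI, CD4 count, log viral load, neutralization breadth).

Group structure is a standardized mean shift per feature family (bNAb
minus no-bNAb, in SD units) on top of Gaussian noise on the measurement
scale, floored at zero, with percentages capped at 100.  The default
effect profile encodes the qualitative pattern the analysis is designed
to recover: elevated ADCD, ADCT, FcR/C1q binding, IgG2/IgG4, total IgG,
CXCL13 and breadth in the bNAb group, a CD4 deficit, and no shift in
viral load (groups matched), ADCP or ADCC.  Features are drawn
independently — no attempt is made to simulate the correlation
structure of real serology panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .sequences import AlignedSequenceSet

DEFAULT_ANTIGENS = ("gp120_ConC", "gp140_CZA1197MB", "gp120_CAP45")
DEFAULT_BINDING_ANTIGENS = ("gp120_ConC", "gp120_CAP45")
FUNCTIONS = ("ADCP", "ADCC", "ADCD", "ADCT")
RECEPTORS = ("FcgRIIa_H131", "FcgRIIa_R131", "FcgRIIb",
             "FcgRIIIa_V158", "FcgRIIIa_F158", "FcgRIIIb_NA2", "C1q")
SUBCLASS_ANTIGEN = "gp120_ConC"

# Standardized bNAb-minus-no-bNAb mean shifts per feature family.
# Directions follow the cohort's univariate findings; a shift of ~1.2 SD
# corresponds to a Mann-Whitney difference detectable at alpha 0.05 with
# 13 vs 10 subjects, matching features reported as significant.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "ADCP": 0.0,
    "ADCC": 0.0,
    "ADCD": 1.2,
    "ADCT": 1.2,
    "FcR": 1.2,
    "C1q": 1.2,
    "IgG1": 0.0,
    "IgG2": 1.5,
    "IgG3": 0.0,
    "IgG4": 1.5,
    "IgG_total": 0.8,
    "CXCL13": 1.2,
    "AID": 1.0,
    "CD4": -1.0,
    "viral_load": 0.0,
    "breadth": 3.0,
}

# (baseline mean, baseline SD) per feature family on its native scale
_PCT_BASE = {"ADCP": (30.0, 8.0), "ADCC": (15.0, 5.0),
             "ADCD": (25.0, 8.0), "ADCT": (10.0, 4.0)}
_MFI_BASE = {"ADCP": (3000.0, 700.0), "ADCC": (2000.0, 500.0),
             "ADCD": (2500.0, 600.0), "ADCT": (2000.0, 500.0)}
_ADCC_BG = (5.0, 1.5)
_BINDING_BASE = (5000.0, 1500.0)
_SUBCLASS_BASE = {"IgG_total": (10000.0, 2500.0), "IgG1": (8000.0, 2000.0),
                  "IgG2": (500.0, 200.0), "IgG3": (1500.0, 500.0),
                  "IgG4": (200.0, 80.0)}
_CLINICAL_BASE = {"CXCL13_pg_ml": (60.0, 25.0), "AID_mfi": (1000.0, 300.0),
                  "CD4_count": (450.0, 120.0), "viral_load_log10": (4.5, 0.7),
                  "breadth_pct": (20.0, 10.0)}
_CLINICAL_FAMILY = {"CXCL13_pg_ml": "CXCL13", "AID_mfi": "AID",
                    "CD4_count": "CD4", "viral_load_log10": "viral_load",
                    "breadth_pct": "breadth"}
# columns where HIV-negative controls are NOT a scaled-down baseline
_CLINICAL_COLS = tuple(_CLINICAL_BASE)


@dataclass
class CohortConfig:
    """Cohort dimensions, effect profile, and noise settings."""

    n_bnab: int = 13
    n_nobnab: int = 10
    n_negative_controls: int = 5
    antigens: tuple[str, ...] = DEFAULT_ANTIGENS
    binding_antigens: tuple[str, ...] = DEFAULT_BINDING_ANTIGENS
    functions: tuple[str, ...] = FUNCTIONS
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    noise_sd: float = 1.0          # multiplier on each family's baseline SD
    plate_effect_sd: float = 0.0   # SD of multiplicative log-normal plate factor
    n_plates: int = 1
    control_scale: float = 0.2     # HIV-specific signal in negative controls
    timepoint_months: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bnab < 2 or self.n_nobnab < 2:
            raise ConfigurationError(
                "need >= 2 subjects per group for variance estimation")
        if self.n_negative_controls < 0:
            raise ConfigurationError("n_negative_controls must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.plate_effect_sd < 0:
            raise ConfigurationError("plate_effect_sd must be non-negative")
        if self.n_plates < 1:
            raise ConfigurationError("n_plates must be >= 1")
        if not self.antigens or not self.functions:
            raise ConfigurationError("antigens and functions must be non-empty")
        unknown = set(self.functions) - set(FUNCTIONS)
        if unknown:
            raise ConfigurationError(f"unknown functions {sorted(unknown)}")


@dataclass
class SyntheticSequenceConfig:
    """Per-site substitution/gap model around a fixed aligned reference."""

    reference_length: int
    n_sequences: int = 10
    per_site_substitution_prob: float = 0.01
    gap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length <= 0:
            raise ConfigurationError("reference_length must be positive")
        if self.n_sequences < 1:
            raise ConfigurationError("n_sequences must be >= 1")
        for name in ("per_site_substitution_prob", "gap_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


def _effect(effects: dict[str, float], family: str) -> float:
    return float(effects.get(family, 0.0))


def _draw(rng, mean, sd, n, shift_sd_units=0.0, lo=0.0, hi=None):
    x = rng.normal(mean + shift_sd_units * sd, sd, size=n)
    x = np.clip(x, lo, hi)
    return x


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one synthetic cohort as a wide per-subject feature table.

    Rows: n_bnab + n_nobnab subjects followed by negative-control donors.
    MFIs and percentages are floored at 0; percentages capped at 100.
    The table's ``attrs`` carry per-plate HIVIG reference scores when
    plate effects are enabled.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    groups = (["bNAb"] * config.n_bnab
              + ["no-bNAb"] * config.n_nobnab
              + ["negative"] * config.n_negative_controls)
    n = len(groups)
    n_subj = config.n_bnab + config.n_nobnab
    is_bnab = np.array([g == "bNAb" for g in groups], dtype=float)
    is_neg = np.array([g == "negative" for g in groups])
    effects = config.effect_sizes
    nm = config.noise_sd

    data: dict[str, np.ndarray] = {}
    data["subject_id"] = np.array(
        [f"SIM{i + 1:03d}" for i in range(n_subj)]
        + [f"NEG{i + 1:03d}" for i in range(n - n_subj)])
    data["group"] = np.array(groups)
    data["timepoint_months"] = np.full(n, config.timepoint_months)
    plates = np.array([f"P{(i % config.n_plates) + 1}" for i in range(n)])
    data["plate"] = plates
    plate_factors = {
        f"P{k + 1}": float(np.exp(rng.normal(0.0, config.plate_effect_sd)))
        if config.plate_effect_sd > 0 else 1.0
        for k in range(config.n_plates)
    }
    row_factor = np.array([plate_factors[p] for p in plates])

    def hiv_specific(mean, sd, shift, lo=0.0, hi=None, scale_mfi=False):
        shifts = shift * is_bnab
        x = rng.normal(mean + shifts * sd, sd * nm, size=n)
        x = np.where(is_neg,
                     rng.normal(mean * config.control_scale,
                                sd * nm * config.control_scale, size=n),
                     x)
        if scale_mfi:
            x = x * row_factor
        return np.clip(x, lo, hi)

    for antigen in config.antigens:
        for fn in config.functions:
            eff = _effect(effects, fn)
            pm, ps = _PCT_BASE[fn]
            mm, ms = _MFI_BASE[fn]
            data[f"{fn}_{antigen}_pct"] = hiv_specific(pm, ps, eff, hi=100.0)
            data[f"{fn}_{antigen}_mfi"] = hiv_specific(mm, ms, eff,
                                                       scale_mfi=True)
            if fn == "ADCC":
                bgm, bgs = _ADCC_BG
                data[f"ADCC_{antigen}_bg_pct"] = np.clip(
                    rng.normal(bgm, bgs * nm, size=n), 0.0, 100.0)

    for antigen in config.binding_antigens:
        for rec in RECEPTORS:
            fam = "C1q" if rec == "C1q" else "FcR"
            bm, bs = _BINDING_BASE
            data[f"{rec}_{antigen}_mfi"] = hiv_specific(
                bm, bs, _effect(effects, fam), scale_mfi=True)

    for sub, (sm, ss) in _SUBCLASS_BASE.items():
        data[f"{sub}_{SUBCLASS_ANTIGEN}_mfi"] = hiv_specific(
            sm, ss, _effect(effects, sub), scale_mfi=True)

    for col, (cm, cs) in _CLINICAL_BASE.items():
        eff = _effect(effects, _CLINICAL_FAMILY[col])
        hi = 100.0 if col == "breadth_pct" else None
        x = _draw(rng, cm, cs * nm, n, shift_sd_units=eff * is_bnab, hi=hi)
        if col in ("viral_load_log10", "breadth_pct"):
            x = np.where(is_neg, 0.0, x)
        data[col] = x

    table = pd.DataFrame(data)
    table.attrs["plate_references"] = {
        p: 100.0 * f for p, f in plate_factors.items()}
    table.attrs["config"] = asdict(config)
    return table


def raw_assay_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide cohort table into the long raw-readout layout
    consumed by :mod:`fcserology.scoring` (one row per
    subject x antigen x function)."""
    rows = []
    pct_cols = [c for c in table.columns
                if c.endswith("_pct") and c.split("_")[0] in FUNCTIONS
                and not c.endswith("_bg_pct")]
    for c in pct_cols:
        fn, antigen = c.split("_", 1)
        antigen = antigen[:-len("_pct")]
        mfi_col = f"{fn}_{antigen}_mfi"
        bg_col = f"ADCC_{antigen}_bg_pct"
        for _, r in table.iterrows():
            rows.append({
                "subject_id": r["subject_id"],
                "group": r["group"],
                "antigen": antigen,
                "function": fn,
                "percent_positive": r[c],
                "mfi": r[mfi_col],
                "background_percent": r[bg_col] if fn == "ADCC" and bg_col in table else 0.0,
                "timepoint_months": r["timepoint_months"],
            })
    return pd.DataFrame(rows)


_BASES = np.array(list("ACGT"))
_ALT = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def random_reference(length: int, seed: int = 0) -> str:
    """Uniform random nucleotide reference of the given length."""
    if length <= 0:
        raise InputError("length must be positive")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_BASES, size=length))


def generate_sequences(config: SyntheticSequenceConfig,
                       reference: str) -> AlignedSequenceSet:
    """Mutate a reference into an aligned set of synthetic sequences.

    Each site independently becomes a gap with ``gap_prob``; otherwise
    it substitutes to one of the 3 alternative bases with
    ``per_site_substitution_prob``.  The true substitution count per
    sequence is recorded in the set's metadata.
    """
    if not reference:
        raise InputError("empty reference sequence")
    reference = reference.upper()
    if len(reference) != config.reference_length:
        raise InputError(
            f"reference length {len(reference)} != configured "
            f"{config.reference_length}")
    if set(reference) - set("ACGT"):
        raise InputError("reference must be over the ACGT alphabet")
    rng = np.random.default_rng(config.seed)
    ids, seqs, true_subs = [], [], {}
    for i in range(config.n_sequences):
        chars = []
        n_sub = 0
        for base in reference:
            if rng.random() < config.gap_prob:
                chars.append("-")
            elif rng.random() < config.per_site_substitution_prob:
                chars.append(_ALT[base][rng.integers(3)])
                n_sub += 1
            else:
                chars.append(base)
        sid = f"sim|{config.seed}|{i + 1:04d}"
        ids.append(sid)
        seqs.append("".join(chars))
        true_subs[sid] = n_sub
    return AlignedSequenceSet(ids, seqs,
                              metadata={"true_substitutions": true_subs})
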