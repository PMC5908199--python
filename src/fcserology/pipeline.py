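"""End-to-end orchestration: simulate/ingest -> score -> composite ->
select -> classify -> report.

Stages communicate through files (CSV/JSON) when an output directory is
given, so each stage is individually inspectable and re-runnable; the
same stage functions are importable for in-memory use.  Every random
stage receives a seed derived deterministically from the master seed,
so a rerun with the same configuration is byte-identical.

The candidate feature set assembled for the multivariate screen mirrors
the design of such cohort studies: 14 FcγR/C1q binding MFIs (7 reagents
x 2 antigens),
3 per-antigen Fc polyfunctionality totals, the IgG subclass diversity
score, 3 relative subclass abundances, the 4 effector-function scores
against the primary antigen, CXCL13, CD4 count, log viral load and
total antigen-specific IgG — 29 candidate variables screened at FDR 5%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composite, multivariate, scoring, sequences, stats, synthetic
from .errors import InputError
from .synthetic import CohortConfig, SyntheticSequenceConfig

PRIMARY_ANTIGEN = "gp120_ConC"


@dataclass
class PipelineConfig:
    """Master configuration; one seed drives every stage."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    sequence: SyntheticSequenceConfig | None = field(
        default_factory=lambda: SyntheticSequenceConfig(
            reference_length=300, n_sequences=10,
            per_site_substitution_prob=0.03))
    fdr: float = 0.05
    n_trees: int = 500
    n_shuffles: int = 2000
    k_pca: int = 2
    seed: int = 0


def _stage_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    names = ("cohort", "sequence", "rf", "permutation")
    return {name: int(rng.integers(2**31)) for name in names}


def assemble_features(table: pd.DataFrame, scored: pd.DataFrame,
                      primary_antigen: str = PRIMARY_ANTIGEN) -> pd.DataFrame:
    """Build the per-subject candidate feature matrix for the screen.

    ``table`` is the wide cohort table (subject rows only, no negative
    controls); ``scored`` is the long thresholded assay-score table.
    """
    subjects = table[table["group"] != "negative"].set_index("subject_id")
    feats = pd.DataFrame(index=subjects.index)

    # per-antigen polyfunctionality totals from the thresholded scores
    for antigen, grp in scored.groupby("antigen"):
        poly = composite.polyfunctionality_from_scores(grp)
        feats[f"polyfunctionality_{antigen}"] = poly["total_z"]

    # effector-function scores against the primary antigen
    primary = scored[scored["antigen"] == primary_antigen]
    for fn, grp in primary.groupby("function"):
        feats[f"{fn}_{primary_antigen}_score"] = (
            grp.set_index("subject_id")["score"])

    # FcγR / C1q binding MFIs
    for col in subjects.columns:
        if col.endswith("_mfi") and any(col.startswith(r)
                                        for r in synthetic.RECEPTORS):
            feats[col] = subjects[col]

    # subclass diversity and relative abundances (scale-invariant ratios,
    # computed on uncorrected MFIs; ratio denominators floored at 1 MFI
    # unit, the instrument detection limit, so a below-detection IgG1
    # yields a large finite ratio rather than an undefined one)
    sub_ant = synthetic.SUBCLASS_ANTIGEN
    profiles = subjects.apply(
        lambda r: composite.SubclassProfile(
            r.name, sub_ant,
            igg_total=max(r[f"IgG_total_{sub_ant}_mfi"], 1.0),
            igg1=max(r[f"IgG1_{sub_ant}_mfi"], 1.0),
            igg2=max(r[f"IgG2_{sub_ant}_mfi"], 0.0),
            igg3=max(r[f"IgG3_{sub_ant}_mfi"], 0.0),
            igg4=max(r[f"IgG4_{sub_ant}_mfi"], 0.0),
        ), axis=1)
    feats["subclass_diversity"] = profiles.map(composite.subclass_diversity_score)
    rel = profiles.map(lambda p: composite.relative_subclass_abundance(p, "to_igg1"))
    for sub in ("IgG2", "IgG3", "IgG4"):
        feats[f"{sub}_rel_IgG1"] = rel.map(lambda d: d[sub])
    feats[f"IgG_total_{sub_ant}_mfi"] = subjects[f"IgG_total_{sub_ant}_mfi"]

    # clinical covariates
    for col in ("CXCL13_pg_ml", "CD4_count", "viral_load_log10"):
        feats[col] = subjects[col]
    return feats


def score_stage(table: pd.DataFrame) -> pd.DataFrame:
    """Score raw assay readouts and subtract per antigen x function
    negative-control thresholds (mean + 3 SD of HIV-negative donors)."""
    raw = synthetic.raw_assay_measurements(table)
    is_ctrl = raw["group"] == "negative"
    controls = raw[is_ctrl] if is_ctrl.any() else None
    scored = scoring.score_table(raw[~is_ctrl], controls)
    return scored


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage on a simulated cohort and return the summary.

    When ``out_dir`` is given, each stage's table and a ``summary.json``
    are written there.
    """
    seeds = _stage_seeds(config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cohort_cfg = CohortConfig(**{**synthetic.asdict(config.cohort),
                                 "seed": seeds["cohort"]})
    table = synthetic.generate_cohort(cohort_cfg)
    subjects = table[table["group"] != "negative"]

    scored = score_stage(table)
    features = assemble_features(table, scored)
    labels = subjects.set_index("subject_id")["group"]

    selection = stats.select_features(
        features.join(labels), fdr=config.fdr, label_col="group")
    selected = selection.loc[selection["selected"], "feature"].tolist()
    fallback = len(selected) < 2
    model_features = features if fallback else features[selected]

    std = multivariate.standardize_features(model_features)
    pca = multivariate.pca_summary(std, k=config.k_pca)
    rf = multivariate.rf_classify(model_features, labels,
                                  n_trees=config.n_trees, seed=seeds["rf"])
    perm = multivariate.permutation_test(
        model_features, labels, n_shuffles=config.n_shuffles,
        n_trees=config.n_trees, seed=seeds["permutation"])

    summary: dict = {
        "seed": config.seed,
        "n_subjects": int(len(subjects)),
        "n_bnab": int((labels == "bNAb").sum()),
        "n_nobnab": int((labels == "no-bNAb").sum()),
        "candidate_features": features.columns.tolist(),
        "selected_features": selected,
        "classification_used_all_features": fallback,
        "polyfunctionality": {
            sid: float(v)
            for sid, v in features[f"polyfunctionality_{PRIMARY_ANTIGEN}"].items()
        },
        "pca_variance_explained_pct": [
            round(100.0 * float(v), 4) for v in pca["variance_explained"]],
        "pca_first_k_cumulative_pct": round(100.0 * pca["cumulative"], 4),
        "confusion_matrix": {"tp": rf.confusion.tp, "fn": rf.confusion.fn,
                             "tn": rf.confusion.tn, "fp": rf.confusion.fp},
        "metrics_pct": {k: round(v, 4) for k, v in rf.metrics.items()},
        "oob_accuracy_pct": round(100.0 * rf.oob_accuracy, 4),
        "gini_importance": [[f, round(v, 6)] for f, v in rf.importance.ranking],
        "permutation": {
            "observed_accuracy_pct": round(perm.observed_accuracy, 4),
            "n_shuffles": perm.n_shuffles,
            "n_exceeding": perm.n_exceeding,
            "exceedance_proportion": perm.exceedance_proportion,
        },
    }

    if config.sequence is not None:
        seq_cfg = SyntheticSequenceConfig(**{
            **synthetic.asdict(config.sequence), "seed": seeds["sequence"]})
        reference = synthetic.random_reference(
            seq_cfg.reference_length, seed=seeds["sequence"])
        seq_set = synthetic.generate_sequences(seq_cfg, reference)
        report = sequences.divergence_report(
            {"sim": seq_set}, {"reference": reference})
        summary["sequence"] = {
            "mean_divergence_pct": round(
                float(report["mean_percent_divergence"].iloc[0]), 4),
            "mean_pairwise_distance_pct": round(
                100.0 * sequences.mean_pairwise_distance(seq_set), 4),
            "n_sequences": len(seq_set),
        }
        if out is not None:
            seq_set.to_fasta(out / "sequences.fasta")
            report.to_csv(out / "divergence.tsv", sep="\t", index=False)

    if out is not None:
        table.to_csv(out / "cohort.csv", index=False)
        scored.to_csv(out / "scored.csv", index=False)
        features.to_csv(out / "features.csv")
        selection.to_csv(out / "selection.csv", index=False)
        pd.DataFrame(rf.importance.ranking,
                     columns=["feature", "mean_decrease_gini"]).to_csv(
                         out / "importance.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
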