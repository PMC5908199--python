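"""Univariate group comparisons, correlations, and FDR feature selection.

Non-parametric throughout: Mann-Whitney U for two groups, Kruskal-Wallis
for several (with Dunn-type pairwise follow-ups), Spearman rank
correlations, and Benjamini-Hochberg control of the false discovery rate
when many features are screened against the outcome group at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InputError

# largest combined sample size for which the exact Mann-Whitney null
# distribution is enumerated (beyond this the normal approximation with
# tie correction is used)
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class CorrelationResult:
    feature_a: str
    feature_b: str
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class FeatureSelection:
    feature: str
    rho: float
    raw_p: float
    adjusted_p: float
    selected: bool


def mann_whitney_u(group_a, group_b) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact p-value (full enumeration of the null permutation distribution)
    when the combined sample size is at most ``EXACT_MW_LIMIT`` and there
    are no ties; otherwise the tie-corrected normal approximation.
    Returns ``{"U": ..., "p_two_sided": ..., "method": ...}`` where U is
    the statistic for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= EXACT_MW_LIMIT and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p_two_sided": float(res.pvalue),
            "method": method}


def kruskal_wallis(groups) -> dict:
    """Kruskal-Wallis H with tie correction; chi-square p-value.

    The all-values-identical case (where the tie correction degenerates)
    is returned as H = 0, p = 1.
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise InputError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return {"H": 0.0, "p": 1.0}
    res = sps.kruskal(*arrays)
    return {"H": float(res.statistic), "p": float(res.pvalue)}


def _dunn_z(groups):
    """Dunn's pairwise z statistics on pooled ranks, with tie correction."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_factor = (n_total * (n_total + 1) / 12.0
                  - tie_term / (12.0 * (n_total - 1)))
    mean_ranks, sizes = [], []
    pos = 0
    for g in arrays:
        mean_ranks.append(ranks[pos:pos + g.size].mean())
        sizes.append(g.size)
        pos += g.size
    pairs, zs = [], []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        pairs.append((i, j))
        zs.append(z)
    return pairs, np.asarray(zs), var_factor, mean_ranks, sizes


def pairwise_posthoc(groups, method: str = "holm") -> pd.DataFrame:
    """Dunn-type pairwise rank comparisons after Kruskal-Wallis.

    ``method`` is a family-wise adjustment: any statsmodels
    ``multipletests`` method name (default ``"holm"``), or ``"tukey"``
    for a studentized-range (HSD-style) test on the rank means.
    Requires at least 3 groups — with 2, use :func:`mann_whitney_u`.
    """
    if len(groups) < 3:
        raise InputError("pairwise post-hoc needs >= 3 groups; "
                         "use mann_whitney_u for two")
    pairs, zs, var_factor, mean_ranks, sizes = _dunn_z(groups)
    k = len(groups)
    if method == "tukey":
        adj = []
        for (i, j), z in zip(pairs, zs):
            se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                adj.append(1.0)
                continue
            q = abs(mean_ranks[i] - mean_ranks[j]) / (se / np.sqrt(2.0))
            adj.append(float(np.clip(sps.studentized_range.sf(q, k, 1e6), 0, 1)))
        raw = [float(2 * sps.norm.sf(abs(z))) for z in zs]
    else:
        raw = [float(2 * sps.norm.sf(abs(z))) for z in zs]
        adj = multipletests(raw, method=method)[1].tolist()
    return pd.DataFrame({
        "group_a": [p[0] for p in pairs],
        "group_b": [p[1] for p in pairs],
        "z": zs,
        "raw_p": raw,
        "adjusted_p": adj,
    })


def spearman(x, y, name_a: str = "x", name_b: str = "y",
             exact: bool = False) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties are average-ranked.  The p-value uses the t-distribution
    approximation; ``exact=True`` enumerates all rank permutations
    (only permitted for n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateInputError("constant vector: Spearman rho undefined")
    rho, p = sps.spearmanr(x, y)
    if exact:
        if x.size > 8:
            raise InputError("exact permutation p only supported for n <= 8")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r, _ = sps.spearmanr(rx, perm)
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    return CorrelationResult(name_a, name_b, float(rho), float(p), int(x.size))


def correlation_matrix(features: pd.DataFrame, alpha: float = 0.05) -> dict:
    """All-pairs Spearman correlations among feature columns.

    Returns ``rho`` and ``p`` (square symmetric DataFrames, unit/zero
    diagonal), plus boolean ``concordant`` / ``discordant`` masks marking
    significantly positive / negative off-diagonal entries at ``alpha``.
    Constant features yield NaN (undefined) entries.
    """
    if len(features) < 3:
        raise InputError("need at least 3 subjects")
    cols = list(features.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        xi = features[cols[i]].to_numpy(dtype=float)
        xj = features[cols[j]].to_numpy(dtype=float)
        if np.unique(xi).size == 1 or np.unique(xj).size == 1:
            rho[i, j] = rho[j, i] = np.nan
            pval[i, j] = pval[j, i] = np.nan
            continue
        r = spearman(xi, xj, cols[i], cols[j])
        rho[i, j] = rho[j, i] = r.rho
        pval[i, j] = pval[j, i] = r.p_value
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)
    off = ~np.eye(k, dtype=bool)
    sig = (p_df.to_numpy() < alpha) & off
    concordant = pd.DataFrame(sig & (rho > 0), index=cols, columns=cols)
    discordant = pd.DataFrame(sig & (rho < 0), index=cols, columns=cols)
    return {"rho": rho_df, "p": p_df,
            "concordant": concordant, "discordant": discordant}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_features(cohort: pd.DataFrame, fdr: float = 0.05,
                    label_col: str = "group", positive: str = "bNAb",
                    features: list[str] | None = None) -> pd.DataFrame:
    """Screen features against the binary outcome group at a given FDR.

    Each feature is Spearman-correlated with the group label coded 0/1
    (equivalent to a rank-biserial association); p-values are BH-adjusted
    across all screened features and a feature is selected when its
    adjusted p falls below ``fdr``.
    """
    if label_col not in cohort.columns:
        raise InputError(f"no {label_col!r} column")
    labels = cohort[label_col]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise InputError("group label must be binary")
    y = (labels == positive).astype(float).to_numpy()
    if positive not in classes:
        raise InputError(f"positive class {positive!r} not present")
    if features is None:
        features = [c for c in cohort.columns
                    if c != label_col and pd.api.types.is_numeric_dtype(cohort[c])]
    if len(features) < 2:
        raise InputError("need at least 2 features to screen")
    rows = []
    for f in features:
        x = cohort[f].to_numpy(dtype=float)
        if np.unique(x).size == 1:
            rows.append((f, np.nan, 1.0))
            continue
        r = spearman(x, y, f, label_col)
        rows.append((f, r.rho, r.p_value))
    raw = np.array([r[2] for r in rows])
    adj = bh_adjust(raw)
    return pd.DataFrame({
        "feature": [r[0] for r in rows],
        "rho": [r[1] for r in rows],
        "raw_p": raw,
        "adjusted_p": adj,
        "selected": adj < fdr,
    })
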