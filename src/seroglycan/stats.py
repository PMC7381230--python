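"""Statistical layer for serum anti-glycan reactivity studies.

Implements the analyses run on the log2 reactivity matrix:

* per-sample median reactivity over the whole array and over decoration
  subgroups (undecorated / fucosylated / sialylated, F1 / F2-F4, S1 / S2);
* three-group (ctrl, UC, CD) comparisons restricted to the two selected
  pairs ctrl-vs-UC and ctrl-vs-CD — one-way ANOVA with Bonferroni-adjusted
  pairwise t on the pooled within-group variance, and Kruskal-Wallis with
  Dunn's post hoc z from mean ranks;
* per-glycan differential reactivity: a two-group linear model per glycan
  with an empirical-Bayes moderated t — the per-glycan residual variance
  s_g^2 (df d) is shrunk toward a prior s0^2 (df d0) estimated across all
  glycans by matching moments of log s_g^2, giving the posterior variance
  s~_g^2 = (d0*s0^2 + d*s_g^2) / (d0 + d) and t with d0 + d degrees of
  freedom;
* the hit rule |logFC| > 2 and raw p <= 0.05, with BH-adjusted p reported
  alongside;
* per-sample IgG-IgM Pearson correlation;
* complete-linkage hierarchical clustering of samples on the distance
  1 - r over the pairwise Pearson correlation matrix, with deterministic
  lowest-index tie-breaking;
* mean-fluorescence normalization by serum IgG concentration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .array import ReactivityMatrix
from .glycans import (
    DecorationClass,
    FucoseBand,
    LibraryPartition,
    SialicBand,
)

logger = logging.getLogger(__name__)

#: Hit rule defaults: |log2 fold change| must exceed this ...
DEFAULT_LOGFC_THRESHOLD = 2.0
#: ... at this raw per-glycan significance level.
DEFAULT_ALPHA = 0.05

SELECTED_PAIRS = (("ctrl", "UC"), ("ctrl", "CD"))
_N_SELECTED_PAIRS = len(SELECTED_PAIRS)

__all__ = [
    "GroupTestResult",
    "DifferentialHit",
    "VariancePrior",
    "ClusterResult",
    "subgroup_median",
    "selected_pair_anova",
    "selected_pair_kw_dunn",
    "fit_differential",
    "select_hits",
    "isotype_correlation",
    "correlation_cluster",
    "normalize_mfi",
]


@dataclass(frozen=True)
class GroupTestResult:
    """One pairwise comparison from a selected-pair multi-group test."""

    comparison: str
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_per_group: dict[str, int]
    degenerate: bool = False


@dataclass(frozen=True)
class DifferentialHit:
    """A glycan passing the fold-change and significance hit rule."""

    glycan_id: str
    composition_label: str
    logfc: float
    t: float
    p_raw: float
    p_adjusted: float
    direction: str  # "increased" | "decreased"


# ---------------------------------------------------------------------------
# Subgroup medians


def subgroup_median(
    matrix: ReactivityMatrix,
    partition: LibraryPartition | None = None,
) -> pd.DataFrame:
    """Per-sample median log2(RFU) over the array and decoration subgroups.

    Returns a long DataFrame (sample_id, subgroup, median, n_glycans) with
    one row per non-empty subgroup.  The ``all`` subgroup uses every glycan
    including unknowns; decoration subgroups exclude unknown and ambiguous
    glycans.  Empty subgroups are omitted with a warning.
    """
    part = partition if partition is not None else matrix.library
    if part is None:
        raise ValueError("subgroup_median needs a library partition")

    subgroups: dict[str, list[str]] = {"all": list(matrix.glycans)}
    for cls in (
        DecorationClass.UNDECORATED,
        DecorationClass.FUCOSYLATED_ONLY,
        DecorationClass.SIALYLATED_ONLY,
        DecorationClass.FUCOSYLATED_SIALYLATED,
    ):
        subgroups[cls.value] = part.ids_in_class(cls)
    for band in (FucoseBand.F1, FucoseBand.F2TO4, FucoseBand.F_GT4):
        subgroups[band.value] = part.ids_in_fucose_band(band)
    for band in (SialicBand.S1, SialicBand.S2, SialicBand.S_GT2):
        subgroups[band.value] = part.ids_in_sialic_band(band)

    present = set(matrix.glycans)
    rows = []
    for key, ids in subgroups.items():
        ids = [g for g in ids if g in present]
        if not ids:
            logger.warning("subgroup %s is empty; omitted", key)
            continue
        medians = matrix.values[ids].median(axis=1)
        for sample_id, med in medians.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "subgroup": key,
                    "median": float(med),
                    "n_glycans": len(ids),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Selected-pair group tests


def _check_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for pair in SELECTED_PAIRS:
        for name in pair:
            if name not in groups:
                raise ValueError(f"missing group {name!r}")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    return groups


def selected_pair_anova(
    values_by_group: Mapping[str, Sequence[float]],
) -> list[GroupTestResult]:
    """One-way ANOVA with Bonferroni pairwise t for ctrl-vs-UC and ctrl-vs-CD.

    Pairwise comparisons use the pooled within-group variance (mean squared
    error over all groups) and its degrees of freedom; the Bonferroni
    factor is exactly 2, the number of selected pairs.  UC-vs-CD is never
    tested.
    """
    groups = _check_groups(values_by_group)
    all_vals = np.concatenate(list(groups.values()))
    n_total, k = len(all_vals), len(groups)
    df_within = n_total - k
    msw = sum(
        np.sum((v - v.mean()) ** 2) for v in groups.values()
    ) / df_within

    results = []
    for a, b in SELECTED_PAIRS:
        va, vb = groups[a], groups[b]
        diff = vb.mean() - va.mean()
        if msw <= 0:
            t_stat, p = 0.0, 1.0
            degenerate = True
        else:
            se = math.sqrt(msw * (1 / len(va) + 1 / len(vb)))
            t_stat = diff / se
            p = 2 * sps.t.sf(abs(t_stat), df_within)
            degenerate = False
        results.append(
            GroupTestResult(
                comparison=f"{a}_vs_{b}",
                method="anova_bonferroni",
                statistic=float(t_stat),
                p_raw=float(p),
                p_adjusted=float(min(1.0, _N_SELECTED_PAIRS * p)),
                n_per_group={g: len(v) for g, v in groups.items()},
                degenerate=degenerate,
            )
        )
    return results


def selected_pair_kw_dunn(
    values_by_group: Mapping[str, Sequence[float]],
) -> list[GroupTestResult]:
    """Kruskal-Wallis with Dunn's post hoc z for the two selected pairs.

    Dunn's z uses mean ranks from the pooled tie-corrected ranking and the
    large-sample normal approximation; the Bonferroni factor is 2.  If all
    pooled values are identical the test is degenerate and p = 1 is
    returned with a flag.
    """
    groups = _check_groups(values_by_group)
    pooled = np.concatenate(list(groups.values()))
    n_total = len(pooled)

    if np.ptp(pooled) == 0:
        return [
            GroupTestResult(
                comparison=f"{a}_vs_{b}",
                method="kw_dunn",
                statistic=0.0,
                p_raw=1.0,
                p_adjusted=1.0,
                n_per_group={g: len(v) for g, v in groups.items()},
                degenerate=True,
            )
            for a, b in SELECTED_PAIRS
        ]

    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for name, vals in groups.items():
        mean_ranks[name] = float(ranks[start : start + len(vals)].mean())
        start += len(vals)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    # Dunn's tie-corrected variance of a mean-rank difference
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    results = []
    for a, b in SELECTED_PAIRS:
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt(var_base * (1 / na + 1 / nb))
        z = (mean_ranks[b] - mean_ranks[a]) / se
        p = 2 * sps.norm.sf(abs(z))
        results.append(
            GroupTestResult(
                comparison=f"{a}_vs_{b}",
                method="kw_dunn",
                statistic=float(z),
                p_raw=float(p),
                p_adjusted=float(min(1.0, _N_SELECTED_PAIRS * p)),
                n_per_group={g: len(v) for g, v in groups.items()},
            )
        )
    return results


# ---------------------------------------------------------------------------
# Differential reactivity (empirical-Bayes moderated t)


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes hyperparameters for the variance prior.

    ``df`` (d0) may be ``inf``, in which case every posterior variance
    equals ``scale`` (s0^2).
    """

    df: float
    scale: float


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Estimate (d0, s0^2) from per-glycan variances by log-moment matching.

    Under the model s_g^2 ~ s0^2 * F(d, d0) scaled, z = log s_g^2 has mean
    log s0^2 + psi(d/2) - psi(d0/2) + log(d0/d) and variance
    psi'(d/2) + psi'(d0/2); matching the observed mean and variance of z
    yields closed-form estimates, with a trigamma inversion for d0.  If the
    observed spread of z is no larger than its sampling component the
    variances are under-dispersed and d0 = inf is returned (all posterior
    variances shrink to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) == 0:
        raise ValueError("all residual variances are zero")
    if len(positive) < len(s2):
        logger.warning(
            "%d of %d residual variances are zero; excluded from prior fit",
            len(s2) - len(positive),
            len(s2),
        )
    z = np.log(positive)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    if n < 2:
        return VariancePrior(df=math.inf, scale=float(np.exp(e_mean)))
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    e_var -= float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0 = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
        return VariancePrior(df=d0, scale=s0)
    return VariancePrior(df=math.inf, scale=float(np.exp(e_mean)))


def posterior_variance(s2: np.ndarray, df: float, prior: VariancePrior) -> np.ndarray:
    """Shrink per-glycan variances toward the prior: (d0 s0^2 + d s^2)/(d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(prior.df):
        return np.full_like(s2, prior.scale)
    return (prior.df * prior.scale + df * s2) / (prior.df + df)


def fit_differential(
    matrix: ReactivityMatrix,
    group_a: str,
    group_b: str,
    use_moderation: bool = True,
) -> pd.DataFrame:
    """Per-glycan two-group differential reactivity with optional moderation.

    For every glycan g: logFC_g = mean_B - mean_A of log2(RFU), pooled
    residual variance s_g^2 with d = nA + nB - 2 degrees of freedom.  With
    moderation on, the prior (d0, s0^2) is estimated across glycans and
    t~_g = logFC_g / (s~_g * sqrt(1/nA + 1/nB)) is referred to a t
    distribution with d0 + d df.  With moderation off (or as fallback when
    every variance is zero) the ordinary pooled two-sample t is used.

    Returns a DataFrame indexed by glycan_id with columns logfc, s2,
    posterior_s2, t, p_raw, p_adjusted (BH), df, plus the composition label
    when the matrix carries a library.
    """
    samples_a = matrix.group_samples(group_a)
    samples_b = matrix.group_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (got {len(samples_a)} {group_a!r}, "
            f"{len(samples_b)} {group_b!r})"
        )
    va = matrix.values.loc[samples_a].to_numpy(dtype=float)
    vb = matrix.values.loc[samples_b].to_numpy(dtype=float)
    na, nb = va.shape[0], vb.shape[0]
    df = na + nb - 2

    mean_a, mean_b = va.mean(axis=0), vb.mean(axis=0)
    logfc = mean_b - mean_a
    ss = ((va - mean_a) ** 2).sum(axis=0) + ((vb - mean_b) ** 2).sum(axis=0)
    s2 = ss / df
    scale = 1.0 / na + 1.0 / nb

    prior: VariancePrior | None = None
    if use_moderation and np.all(s2 == 0):
        logger.warning(
            "all per-glycan variances are zero; falling back to ordinary t"
        )
        use_moderation = False

    if use_moderation:
        prior = fit_variance_prior(s2, df)
        post_s2 = posterior_variance(s2, df, prior)
        total_df = prior.df + df
    else:
        post_s2 = s2
        total_df = df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(post_s2 * scale)
    bad = ~np.isfinite(t)
    if bad.any():  # zero posterior variance: t is 0 or +/- inf by sign
        t = t.copy()
        t[bad & (logfc == 0)] = 0.0
        t[bad & (logfc > 0)] = np.inf
        t[bad & (logfc < 0)] = -np.inf
    if math.isinf(total_df):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), total_df)
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "logfc": logfc,
            "s2": s2,
            "posterior_s2": post_s2,
            "t": t,
            "p_raw": p,
            "p_adjusted": p_adj,
            "df": float(df),
        },
        index=pd.Index(matrix.glycans, name="glycan_id"),
    )
    out.attrs["prior"] = prior
    out.attrs["groups"] = (group_a, group_b)
    out.attrs["n_per_group"] = {group_a: na, group_b: nb}
    if matrix.library is not None:
        out["composition_label"] = [
            matrix.library.compositions[g].source_label
            if g in matrix.library.compositions
            else ""
            for g in out.index
        ]
    return out


def select_hits(
    results: pd.DataFrame,
    logfc_threshold: float = DEFAULT_LOGFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> list[DifferentialHit]:
    """Apply the hit rule |logFC| > threshold AND raw p <= alpha.

    Hits are sorted by |logFC| descending and labelled increased/decreased
    by the sign of logFC; BH-adjusted p values are carried along but do not
    enter the rule.
    """
    mask = (results["logfc"].abs() > logfc_threshold) & (results["p_raw"] <= alpha)
    selected = results[mask].sort_values(
        by="logfc", key=lambda s: s.abs(), ascending=False
    )
    hits = []
    for glycan_id, row in selected.iterrows():
        hits.append(
            DifferentialHit(
                glycan_id=str(glycan_id),
                composition_label=str(row.get("composition_label", "")),
                logfc=float(row["logfc"]),
                t=float(row["t"]),
                p_raw=float(row["p_raw"]),
                p_adjusted=float(row["p_adjusted"]),
                direction="increased" if row["logfc"] > 0 else "decreased",
            )
        )
    return hits


def hits_to_frame(hits: Sequence[DifferentialHit]) -> pd.DataFrame:
    """Hit list as a table (composition, logFC, raw p, adjusted p, direction)."""
    return pd.DataFrame(
        [
            {
                "glycan_id": h.glycan_id,
                "composition": h.composition_label,
                "logfc": h.logfc,
                "p_raw": h.p_raw,
                "p_adjusted": h.p_adjusted,
                "direction": h.direction,
            }
            for h in hits
        ]
    )


# ---------------------------------------------------------------------------
# Isotype correlation


def isotype_correlation(
    matrix_igg: ReactivityMatrix, matrix_igm: ReactivityMatrix
) -> pd.DataFrame:
    """Per-sample Pearson correlation of IgG and IgM reactivity over glycans.

    Returns a DataFrame (sample_id, r, p, degenerate); zero-variance
    vectors give r = NaN with the degenerate flag set.
    """
    if list(matrix_igg.glycans) != list(matrix_igm.glycans):
        common = [g for g in matrix_igg.glycans if g in set(matrix_igm.glycans)]
        if not common:
            raise ValueError("no shared glycans between isotype matrices")
    else:
        common = list(matrix_igg.glycans)
    shared_samples = [s for s in matrix_igg.samples if s in set(matrix_igm.samples)]
    if not shared_samples:
        raise ValueError("no shared samples between isotype matrices")

    rows = []
    for sample in shared_samples:
        x = matrix_igg.values.loc[sample, common].to_numpy(dtype=float)
        y = matrix_igm.values.loc[sample, common].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                {"sample_id": sample, "r": np.nan, "p": np.nan, "degenerate": True}
            )
            continue
        r, p = sps.pearsonr(x, y)
        rows.append(
            {"sample_id": sample, "r": float(r), "p": float(p), "degenerate": False}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation-based complete-linkage clustering


@dataclass
class ClusterResult:
    """Complete-linkage clustering of samples on 1 - Pearson r."""

    correlation: pd.DataFrame
    merges: list[tuple[int, int, float]]
    linkage: np.ndarray
    sample_order: list[str]


def correlation_cluster(matrix: ReactivityMatrix | pd.DataFrame) -> ClusterResult:
    """Cluster samples by complete linkage on the correlation distance.

    The pairwise Pearson correlation matrix R of all samples (symmetric,
    unit diagonal) is converted to the distance D = 1 - R and clusters are
    merged agglomeratively under the complete-linkage rule (cluster
    distance = max member distance).  Ties are broken deterministically by
    the lexicographically smallest pair of cluster representatives, where a
    cluster's representative is its smallest original sample index.

    Returns the merge sequence as (i, j, height) over scipy-style cluster
    ids (originals 0..n-1, the k-th new cluster n+k), a scipy-compatible
    linkage matrix and the dendrogram leaf order.
    """
    values = matrix.values if isinstance(matrix, ReactivityMatrix) else matrix
    samples = list(values.index)
    n = len(samples)
    if n < 2:
        raise ValueError("clustering needs at least two samples")
    data = values.to_numpy(dtype=float)
    sd = data.std(axis=1)
    constant = [samples[i] for i in np.nonzero(sd == 0)[0]]
    if constant:
        raise ValueError(
            f"constant sample vectors have undefined correlations: {constant}"
        )
    corr = np.corrcoef(data)
    corr_df = pd.DataFrame(corr, index=samples, columns=samples)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)

    # active cluster -> (scipy id, member leaf indices, representative)
    active: dict[int, tuple[int, list[int]]] = {i: (i, [i]) for i in range(n)}
    cluster_dist = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    linkage_rows = []
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    trees: dict[int, object] = {i: i for i in range(n)}
    next_id = n
    keys = sorted(active.keys())
    while len(keys) > 1:
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = cluster_dist[(min(a, b), max(a, b))]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        id_a, id_b = active[a][0], active[b][0]
        merges.append((id_a, id_b, d))
        linkage_rows.append(
            [float(id_a), float(id_b), float(d), float(len(members[id_a]) + len(members[id_b]))]
        )
        merged_members = members[id_a] + members[id_b]
        members[next_id] = merged_members
        trees[next_id] = (trees[id_a], trees[id_b])
        rep = min(a, b)
        # complete linkage: distance to the merged cluster is the max
        for other in keys:
            if other in (a, b):
                continue
            d_new = max(
                cluster_dist[(min(a, other), max(a, other))],
                cluster_dist[(min(b, other), max(b, other))],
            )
            cluster_dist[(min(rep, other), max(rep, other))] = d_new
        active[rep] = (next_id, merged_members)
        del active[max(a, b)]
        if rep != min(a, b):  # pragma: no cover - rep is always min(a, b)
            raise AssertionError
        next_id += 1
        keys = sorted(active.keys())

    def _leaves(tree) -> list[int]:
        if isinstance(tree, int):
            return [tree]
        left, right = tree
        return _leaves(left) + _leaves(right)

    root = trees[next_id - 1]
    order = [samples[i] for i in _leaves(root)]
    return ClusterResult(
        correlation=corr_df,
        merges=merges,
        linkage=np.asarray(linkage_rows, dtype=float),
        sample_order=order,
    )


# ---------------------------------------------------------------------------
# MFI normalization


def normalize_mfi(mfi: float | np.ndarray, igg_concentration: float | np.ndarray):
    """Normalize mean fluorescence intensity by serum IgG concentration.

    Units: fluorescence per (mass/volume).  Doubling both inputs leaves the
    result unchanged; non-positive concentrations are an error.
    """
    conc = np.asarray(igg_concentration, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("IgG concentration must be positive")
    out = np.asarray(mfi, dtype=float) / conc
    if np.isscalar(mfi) or (isinstance(mfi, (int, float)) and conc.ndim == 0):
        return float(out)
    return out
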