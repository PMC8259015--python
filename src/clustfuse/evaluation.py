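"""Evaluation statistics for consensus clusterings.

Four analyses: adjusted Rand index between partitions; a permutation log-rank
test for differential overall survival across clusters; clinical-label
enrichment in clusters (chi-square for discrete labels, Kruskal-Wallis for
numeric ones, with empirical permutation p-values); and per-feature
Kruskal-Wallis differential testing with Benjamini-Hochberg FDR control for
ranking, e.g., differentially expressed genes across consensus clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from ._stats import (
    chi2_stat_batch,
    kruskal_stat_batch,
    logrank_chi2_batch,
    permutation_pvalue,
)

__all__ = [
    "EnrichmentResult",
    "ari",
    "logrank_permutation",
    "clinical_enrichment",
    "per_cluster_label_direction",
    "feature_kw_fdr",
]


@dataclass
class EnrichmentResult:
    """Outcome of one clinical-label enrichment test."""

    label: str
    kind: str  # "discrete" | "numeric"
    statistic: float | None
    p_empirical: float | None
    n_used: int
    dropped: bool
    significant: bool = False
    note: str = ""


def ari(p1: dict[str, str], p2: dict[str, str]) -> float:
    """Adjusted Rand index between two partitions on their sample intersection.

    Chance-corrected pairwise agreement: 1 for identical partitions (up to
    label renaming), about 0 for independent ones.
    """
    common = sorted(set(p1) & set(p2))
    if len(common) < 2:
        raise ValueError(
            f"partitions share only {len(common)} sample(s); need at least 2"
        )
    return float(adjusted_rand_score([p1[s] for s in common], [p2[s] for s in common]))


def _partition_codes(partition: dict[str, str], samples: list[str]) -> np.ndarray:
    labels = sorted({partition[s] for s in samples})
    index = {lab: i for i, lab in enumerate(labels)}
    return np.array([index[partition[s]] for s in samples]), len(labels)


def logrank_permutation(
    survival: pd.DataFrame,
    partition: dict[str, str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> dict:
    """Permutation log-rank test of survival differences across clusters.

    The observed statistic is the K-sample log-rank chi-square; cluster labels
    are then permuted over samples ``n_perm`` times and the empirical p-value
    is the add-one exceedance fraction.

    ``survival`` needs columns ``sample_id``, ``time`` (>= 0) and ``event``
    (1 = event observed, 0 = censored).  Samples without survival data or
    outside the partition are excluded.
    """
    sub = survival[survival["sample_id"].isin(partition)].dropna(
        subset=["time", "event"]
    )
    if (sub["time"] < 0).any():
        raise ValueError("negative survival times")
    samples = sub["sample_id"].tolist()
    codes_tuple = _partition_codes(partition, samples)
    codes, k = codes_tuple
    if k < 2:
        raise ValueError("log-rank test needs at least 2 clusters with survival data")
    if not sub["event"].astype(bool).any():
        raise ValueError("all observations censored; log-rank statistic undefined")

    time = sub["time"].to_numpy(float)
    event = sub["event"].to_numpy(float)
    rng = np.random.default_rng(seed)
    stat, p = permutation_pvalue(
        lambda g: logrank_chi2_batch(time, event, g, k), codes, n_perm, rng
    )
    return {"statistic": stat, "p_empirical": p, "n_used": len(samples),
            "n_clusters": k, "n_perm": n_perm}


def clinical_enrichment(
    clinical: pd.DataFrame,
    column_kinds: dict[str, str],
    partition: dict[str, str],
    n_perm: int = 100_000,
    seed: int = 0,
    alpha: float = 0.01,
    max_missing: float = 0.5,
) -> list[EnrichmentResult]:
    """Per-label enrichment of clinical covariates in consensus clusters.

    Discrete labels use the chi-square statistic of the clusters x categories
    contingency table; numeric labels use the Kruskal-Wallis statistic.  Both
    p-values are empirical, from permuting cluster labels over the samples
    carrying a value.  Labels missing for more than ``max_missing`` of the
    partitioned samples are dropped; constant labels are reported
    non-significant with a note.
    """
    rng = np.random.default_rng(seed)
    pop = [s for s in clinical["sample_id"] if s in partition]
    clin = clinical.set_index("sample_id").loc[pop]
    results: list[EnrichmentResult] = []

    for label, kind in column_kinds.items():
        if kind not in ("discrete", "numeric"):
            raise ValueError(f"label {label!r}: unknown kind {kind!r}")
        col = clin[label]
        present = col.notna()
        if len(pop) == 0 or (1 - present.mean()) > max_missing:
            results.append(EnrichmentResult(label, kind, None, None,
                                            int(present.sum()), dropped=True,
                                            note="missing-rate filter"))
            continue
        samples = col.index[present].tolist()
        values = col[present]
        codes, k = _partition_codes(partition, samples)
        if k < 2 or values.nunique() < 2:
            results.append(EnrichmentResult(label, kind, None, None, len(samples),
                                            dropped=False,
                                            note="constant label or single cluster; "
                                                 "statistic undefined"))
            continue
        if kind == "discrete":
            cats = pd.Categorical(values.astype(str))
            cat_codes = cats.codes.astype(np.int64)
            n_cat = len(cats.categories)
            fn = lambda g: chi2_stat_batch(g, cat_codes, k, n_cat)  # noqa: E731
        else:
            num = values.to_numpy(float)
            fn = lambda g: kruskal_stat_batch(num, g, k)  # noqa: E731
        stat, p = permutation_pvalue(fn, codes, n_perm, rng)
        results.append(EnrichmentResult(label, kind, stat, p, len(samples),
                                        dropped=False, significant=p < alpha))
    return results


def per_cluster_label_direction(
    clinical: pd.DataFrame, label: str, partition: dict[str, str]
) -> pd.DataFrame:
    """Standardized residuals of the clusters x categories table for one label.

    Residual ``(O - E) / sqrt(E)`` per (cluster, category) cell; a positive
    sign marks over-representation of the category in the cluster, a negative
    sign under-representation.
    """
    clin = clinical.set_index("sample_id")
    rows = []
    for s, lab in partition.items():
        if s in clin.index and pd.notna(clin.at[s, label]):
            rows.append((lab, str(clin.at[s, label])))
    if not rows:
        raise ValueError(f"no sample carries a value for label {label!r}")
    df = pd.DataFrame(rows, columns=["cluster", "category"])
    obs = pd.crosstab(df["cluster"], df["category"]).astype(float)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.values.sum()
    resid = (obs.values - exp) / np.sqrt(exp)
    return pd.DataFrame(resid, index=obs.index, columns=obs.columns)


def feature_kw_fdr(
    matrix: pd.DataFrame,
    partition: dict[str, str],
    alpha: float = 0.001,
    top_n: int = 1000,
) -> pd.DataFrame:
    """Rank features differential across clusters (Kruskal-Wallis + BH FDR).

    ``matrix`` is samples x features (index = sample_id).  Each feature gets a
    Kruskal-Wallis p-value across the consensus clusters; p-values are BH
    adjusted, features with adjusted p < ``alpha`` are kept, and the ``top_n``
    most significant are returned, most significant first.  Constant features
    get p = 1 by convention.
    """
    samples = [s for s in matrix.index if s in partition]
    if len({partition[s] for s in samples}) < 2:
        raise ValueError("need at least 2 clusters among the profiled samples")
    sub = matrix.loc[samples]
    groups = pd.Series([partition[s] for s in samples], index=samples)
    split = [sub[groups == g] for g in sorted(groups.unique())]

    stats_, pvals = [], []
    for feat in sub.columns:
        vals = [blk[feat].to_numpy(float) for blk in split]
        pooled = np.concatenate(vals)
        if np.unique(pooled[~np.isnan(pooled)]).size < 2:
            stats_.append(0.0)
            pvals.append(1.0)
            continue
        res = sps.kruskal(*[v[~np.isnan(v)] for v in vals])
        stats_.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    padj = sps.false_discovery_control(pvals, method="bh")
    out = pd.DataFrame({
        "feature": sub.columns,
        "statistic": stats_,
        "p_value": pvals,
        "p_adjusted": padj,
    })
    out = out[out["p_adjusted"] < alpha].sort_values(
        ["p_adjusted", "p_value", "feature"]
    )
    return out.head(top_n).reset_index(drop=True)
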