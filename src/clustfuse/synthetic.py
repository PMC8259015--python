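"""Synthetic input-clustering ensembles with planted structure.

Emulates the study design the method targets: a planted ground-truth subtype
partition of a patient cohort; an ensemble of input clusterings laid out as
methods x omics (five methods on three data sources by default); per-clustering
label noise; per-omics signal strength (an omics may reflect the planted
structure or an unrelated partition of its own); per-omics missing samples
(partial data, shared by every method run on that omics); and cluster-correlated
survival and clinical covariates for the downstream biological evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import InputClustering

__all__ = [
    "EnsembleConfig",
    "plant_truth",
    "make_ensemble",
    "simulate_survival",
    "simulate_clinical",
]

DEFAULT_METHODS = ("method1", "method2", "method3", "method4", "method5")
DEFAULT_OMICS = ("expression", "mirna", "methylation")


@dataclass
class EnsembleConfig:
    """Parameters of one synthetic benchmark.

    Defaults mirror a realistic multi-omics subtyping cohort: 300 patients,
    4 planted subtypes, 5 clustering methods on each of 3 omics (15 input
    clusterings), 20% per-clustering label noise, 90% chance an omics carries
    the planted signal, 20% of samples unmeasured per omics, and a 10% chance
    a clustering splits or merges clusters.
    """

    n_samples: int = 300
    k_true: int = 4
    cluster_size_weights: tuple[float, ...] | None = None
    methods: tuple[str, ...] = DEFAULT_METHODS
    omics: tuple[str, ...] = DEFAULT_OMICS
    noise_rate: float | dict[tuple[str, str], float] = 0.2
    omics_signal: float | dict[str, float] = 0.9
    missing_rate: float | dict[str, float] = 0.2
    split_merge_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.n_samples < 2 * self.k_true:
            raise ValueError("need n_samples >= 2 * k_true")
        for name, val in (("noise_rate", self.noise_rate),
                          ("omics_signal", self.omics_signal),
                          ("missing_rate", self.missing_rate),
                          ("split_merge_rate", self.split_merge_rate)):
            vals = val.values() if isinstance(val, dict) else [val]
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} values must lie in [0, 1]")

    def _noise(self, method: str, omics: str) -> float:
        if isinstance(self.noise_rate, dict):
            return self.noise_rate[(method, omics)]
        return self.noise_rate

    def _signal(self, omics: str) -> float:
        if isinstance(self.omics_signal, dict):
            return self.omics_signal[omics]
        return self.omics_signal

    def _missing(self, omics: str) -> float:
        if isinstance(self.missing_rate, dict):
            return self.missing_rate[omics]
        return self.missing_rate


def _sample_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def _draw_partition(
    samples: list[str], k: int, weights: np.ndarray, rng: np.random.Generator,
    prefix: str, max_retries: int = 100,
) -> dict[str, str]:
    for _ in range(max_retries):
        draw = rng.choice(k, size=len(samples), p=weights)
        if len(np.unique(draw)) == k:
            return {s: f"{prefix}{c + 1}" for s, c in zip(samples, draw)}
    raise RuntimeError(
        f"could not draw a partition with all {k} clusters occupied "
        f"after {max_retries} attempts"
    )


def plant_truth(config: EnsembleConfig) -> dict[str, str]:
    """Plant the ground-truth partition: multinomial assignment by size weights."""
    rng = np.random.default_rng(config.seed)
    if config.cluster_size_weights is None:
        weights = np.full(config.k_true, 1.0 / config.k_true)
    else:
        weights = np.asarray(config.cluster_size_weights, dtype=float)
        if weights.size != config.k_true or (weights <= 0).any():
            raise ValueError("cluster_size_weights must be k_true positive numbers")
        weights = weights / weights.sum()
    return _draw_partition(_sample_ids(config.n_samples), config.k_true, weights,
                           rng, prefix="T")


def _add_label_noise(
    assignment: dict[str, str], rate: float, rng: np.random.Generator
) -> dict[str, str]:
    """Relabel a ``rate`` fraction of samples to a uniformly chosen *other* label."""
    labels = sorted(set(assignment.values()))
    if len(labels) < 2 or rate == 0:
        return dict(assignment)
    samples = sorted(assignment)
    n_flip = int(round(rate * len(samples)))
    out = dict(assignment)
    flip = rng.choice(len(samples), size=n_flip, replace=False)
    for i in flip:
        s = samples[i]
        others = [lab for lab in labels if lab != out[s]]
        out[s] = others[rng.integers(len(others))]
    # noise must not silently empty a cluster
    for lab in labels:
        if lab not in out.values():
            s = samples[int(rng.integers(len(samples)))]
            out[s] = lab
    return out


def _split_or_merge(
    assignment: dict[str, str], rng: np.random.Generator
) -> dict[str, str]:
    labels = sorted(set(assignment.values()))
    out = dict(assignment)
    if len(labels) >= 3 and rng.random() < 0.5:  # merge two clusters
        a, b = rng.choice(len(labels), size=2, replace=False)
        for s, lab in out.items():
            if lab == labels[b]:
                out[s] = labels[a]
        return out
    # split the largest cluster in two
    sizes = {lab: sum(1 for v in out.values() if v == lab) for lab in labels}
    target = max(sorted(labels), key=lambda lab: sizes[lab])
    members = sorted(s for s, lab in out.items() if lab == target)
    if len(members) < 2:
        return out
    half = rng.choice(len(members), size=len(members) // 2, replace=False)
    for i in half:
        out[members[i]] = f"{target}.split"
    return out


def make_ensemble(
    truth: dict[str, str], config: EnsembleConfig
) -> list[InputClustering]:
    """Generate one input clustering per (method, omics) cell.

    Per omics: an alternative (signal-free) partition and a shared missing-sample
    set are drawn once; every method of that omics covers the same samples.
    Per clustering: start from truth with probability ``omics_signal`` (else the
    omics' alternative partition), apply label noise and the occasional
    split/merge perturbation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = sorted(truth)
    weights = np.full(config.k_true, 1.0 / config.k_true)

    clusterings: list[InputClustering] = []
    for omics in config.omics:
        alternative = _draw_partition(samples, config.k_true, weights, rng,
                                      prefix=f"alt_{omics}_")
        n_missing = int(round(config._missing(omics) * len(samples)))
        missing = set()
        if n_missing:
            missing = {samples[i] for i in
                       rng.choice(len(samples), size=n_missing, replace=False)}
        covered = [s for s in samples if s not in missing]
        if len(covered) < 2:
            raise ValueError(f"missing_rate for omics {omics!r} leaves <2 samples")
        for method in config.methods:
            base = truth if rng.random() < config._signal(omics) else alternative
            assign = {s: base[s] for s in covered}
            assign = _add_label_noise(assign, config._noise(method, omics), rng)
            if rng.random() < config.split_merge_rate:
                assign = _split_or_merge(assign, rng)
            clusterings.append(InputClustering(
                name=f"{method}.{omics}",
                method=method,
                omics=frozenset({omics}),
                assignment=assign,
            ))
    return clusterings


def simulate_survival(
    truth: dict[str, str],
    hazards: dict[str, float],
    censor_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with cluster-specific hazard rates.

    Censoring is independent exponential with its rate chosen so the expected
    censored fraction is about ``censor_rate`` at the mean hazard;
    ``censor_rate = 0`` disables censoring entirely.
    """
    if any(h <= 0 for h in hazards.values()):
        raise ValueError("hazard rates must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = sorted(truth)
    rates = np.array([hazards[truth[s]] for s in samples])
    event_time = rng.exponential(1.0 / rates)
    if censor_rate == 0:
        return pd.DataFrame({"sample_id": samples, "time": event_time,
                             "event": np.ones(len(samples), dtype=int)})
    c_rate = censor_rate * rates.mean() / (1 - censor_rate)
    censor_time = rng.exponential(1.0 / c_rate, size=len(samples))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"sample_id": samples, "time": time, "event": event})


def simulate_clinical(
    truth: dict[str, str],
    n_discrete: int = 2,
    n_numeric: int = 2,
    effect: float | dict[str, float] = 1.0,
    missing_frac: float = 0.0,
    n_categories: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Cluster-correlated clinical covariates.

    Discrete labels draw from cluster-tilted categorical distributions (each
    cluster prefers one category with a weight growing in ``effect``); numeric
    labels are normal with cluster-shifted means (shift = effect * cluster
    index).  ``effect = 0`` gives labels independent of the clusters.  Returns
    the wide table and the column-kind declaration for the enrichment tests.
    """
    rng = np.random.default_rng(seed)
    samples = sorted(truth)
    labels = sorted(set(truth.values()))
    cluster_idx = np.array([labels.index(truth[s]) for s in samples])

    data: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for d in range(n_discrete):
        name = f"discrete_{d + 1}"
        eff = effect[name] if isinstance(effect, dict) else effect
        probs = np.ones((len(labels), n_categories))
        for ci in range(len(labels)):
            probs[ci, (ci + d) % n_categories] += eff * n_categories
        probs /= probs.sum(axis=1, keepdims=True)
        draws = np.array([
            rng.choice(n_categories, p=probs[ci]) for ci in cluster_idx
        ])
        data[name] = np.array([f"cat{c + 1}" for c in draws], dtype=object)
        kinds[name] = "discrete"
    for d in range(n_numeric):
        name = f"numeric_{d + 1}"
        eff = effect[name] if isinstance(effect, dict) else effect
        data[name] = eff * cluster_idx + rng.normal(size=len(samples))
        kinds[name] = "numeric"

    df = pd.DataFrame({"sample_id": samples, **data})
    if missing_frac > 0:
        for col in kinds:
            n_miss = int(round(missing_frac * len(samples)))
            miss = rng.choice(len(samples), size=n_miss, replace=False)
            if kinds[col] == "numeric":
                df.loc[df.index[miss], col] = np.nan
            else:
                df[col] = df[col].astype(object)
                df.loc[df.index[miss], col] = None
    return df, kinds
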