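"""Biological evaluation of a consensus clustering.

Simulates cluster-correlated survival (distinct exponential hazards per
planted subtype) and clinical covariates, then asks whether the consensus
clusters separate survival (permutation log-rank test) and are enriched for
clinical labels (chi-square / Kruskal-Wallis with empirical p-values).
"""

from clustfuse import (
    ConsensusParams,
    EnsembleConfig,
    IntegrationScenario,
    build_integration_graph,
    build_support_graph,
    clinical_enrichment,
    logrank_permutation,
    make_ensemble,
    plant_truth,
    run_consensus,
    simulate_clinical,
    simulate_survival,
)

cfg = EnsembleConfig(n_samples=200, k_true=3, noise_rate=0.2, seed=7)
truth = plant_truth(cfg)
ensemble = make_ensemble(truth, cfg)
ig = build_integration_graph(build_support_graph(ensemble),
                             IntegrationScenario.select(ensemble))
result = run_consensus(ig, ConsensusParams(min_size_cluster=0.05,
                                           min_size_consensus=0.5), seed=1)
print(f"consensus: {len(result.cluster_sizes())} clusters, wMQ={result.wmq:.3f}")

# survival: hazards 1, 2, 4 per planted subtype, ~20% censoring
hazards = {lab: 2.0**i for i, lab in enumerate(sorted(set(truth.values())))}
survival = simulate_survival(truth, hazards, censor_rate=0.2, seed=11)
out = logrank_permutation(survival, result.assignment, n_perm=10_000, seed=2)
print(f"\npermutation log-rank: chi2={out['statistic']:.1f}, "
      f"p={out['p_empirical']:.2e} over {out['n_perm']} permutations "
      f"({out['n_used']} patients)")

# clinical labels: one strongly tilted discrete + numeric pair, one missing-heavy
clinical, kinds = simulate_clinical(truth, n_discrete=1, n_numeric=1,
                                    effect=1.5, seed=12)
results = clinical_enrichment(clinical, kinds, result.assignment,
                              n_perm=10_000, seed=3)
print("\nclinical-label enrichment (empirical p at alpha 0.01):")
for r in results:
    flag = "significant" if r.significant else "not significant"
    print(f"  {r.label} ({r.kind}): stat={r.statistic:.1f}, "
          f"p={r.p_empirical:.2e} -> {flag}")
# Small p-values mean the clusters capture real covariate structure: here the
# covariates were generated from the planted subtypes, so both should light up.
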