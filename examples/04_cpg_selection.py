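"""Which CpGs do the clocks agree on?

Trains several clocks per tissue (one per leave-one-dataset-out fold),
thresholds small coefficients, drops unstable CpGs, and summarizes the
consensus selections as sets, genes and three-set overlap counts.
"""

import methclock as mc

study, truth = mc.simulate_study(mc.GeneratorConfig(
    tissues=("A12.207.152",),
    datasets_per_tissue=4,
    samples_per_dataset=100,
    seed=3,
))
plan = mc.ExperimentPlan(penalties=(mc.ELASTIC_NET,), ladder=(), seed=3)
result = mc.run_full_benchmark(study, plan)

profile = mc.build_selection_profile(
    {f"fold_{k[1]}": m for k, m in result.models.items()}, "A12.207.152")
print(f"selection profile: {profile.n_clocks} clocks x "
      f"{profile.coefficients.shape[1]} CpGs")

profile = mc.stability_filter(mc.threshold_coefficients(profile))
all_set, any_set = mc.consensus_sets(profile)
planted = truth.all_clock_cpgs()
print(f"after |c| <= 0.1 thresholding and 10% stability filter: "
      f"{profile.coefficients.shape[1]} CpGs")
print(f"selected by every clock: {len(all_set)}, by at least one: {len(any_set)}")
print(f"planted CpGs among the union: {len(any_set & planted)}/{len(planted)}")

genes = mc.map_to_genes(any_set, study.probes)
print(f"genes behind the union selection: {len(genes)}")

clocks = sorted(profile.coefficients.index)
sets = [set(profile.coefficients.columns[profile.coefficients.loc[c] != 0])
        for c in clocks[:3]]
counts = mc.overlap_counts(*sets, labels=tuple(clocks[:3]))
print(f"three-clock Venn regions (exclusive counts): "
      f"only-first={counts.only_a}, only-second={counts.only_b}, "
      f"only-third={counts.only_c}, all-three={counts.abc}")
print("(a large triple-overlap region means the folds agree on a core "
      "set of age-associated CpGs)")
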