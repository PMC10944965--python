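"""Simulate a small methylation study and train one elastic-net age clock.

Builds a two-dataset blood study with a planted age signal, runs the
preprocessing pipeline (imputation, probe filters, logit2 transform), trains
a clock on one dataset and validates it on the other.
"""

import methclock as mc

config = mc.GeneratorConfig(
    tissues=("A12.207.152",),  # blood
    datasets_per_tissue=2,
    samples_per_dataset=80,
    n_background_cpgs=100,
    n_shared_clock_cpgs=15,
    n_tissue_specific_clock_cpgs=0,
    noise_sd=0.5,
    seed=7,
)
study, truth = mc.simulate_study(config)
print(f"study: {study.n_probes} probes x {study.n_samples} samples, "
      f"{len(truth.shared_cpgs)} planted clock CpGs")

sheet = study.samples
train = study.subset_samples(list(sheet[sheet.gse_id == "GSE100"].sample_id))
valid = study.subset_samples(list(sheet[sheet.gse_id == "GSE101"].sample_id))

m_train, m_valid, report = mc.preprocess_pair(train, valid)
print(f"probes retained after filtering: {m_train.shape[0]} "
      f"(removed per rule: {report.counts})")

ages = sheet.set_index("sample_id")["age"]
model = mc.fit_clock(m_train, ages.loc[m_train.columns], mc.ELASTIC_NET, seed=0)
print(f"clock: {len(model.coefficients)} non-zero CpGs at lambda = "
      f"{model.lambda_selected:.3f}")

recovered = model.nonzero_cpgs() & set(truth.shared_cpgs)
print(f"planted CpGs recovered: {len(recovered)}/{len(truth.shared_cpgs)}")

record = mc.score_clock(model, m_valid, ages.loc[m_valid.columns],
                        split="validation", gse_id="GSE101")
print(f"validation: adjusted R2 = {record.adjusted_r2:.3f}, "
      f"RMSE = {record.rmse:.2f} years")
print("(adjusted R2 near 1 and RMSE of a few years: the clock transfers "
      "cleanly to an unseen dataset)")
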