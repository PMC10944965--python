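"""Prepackaged synthetic benchmark experiments and their headline analyses.

Each experiment simulates a study under the package's standard conditions,
runs the LODO benchmark and fits the corresponding mixed-model contrasts.
These are the four qualitative findings the pipeline is designed to probe:

1. validation performance increases with training sample size;
2. lasso / elastic-net / ridge perform comparably (penalty contrast);
3. sex-specific training buys nothing unless a sex-modulated signal exists;
4. tissue-trained clocks beat a blood-trained clock transferred across
   tissues when tissue-specific age signal exists.

p-values within each analysis family are BY-adjusted together (the family
is the set of contrasts reported side by side: responses for the size
analysis, tissues for the penalty and sex analyses, tissues x responses for
the tissue-specific analysis).
"""

from __future__ import annotations

import pandas as pd

from .clock import ELASTIC_NET, LASSO
from .harness import BLOOD_CODE, BenchmarkResult, ExperimentPlan, run_full_benchmark
from .meta import ComparisonResult, MixedModelSpec, adjust_family, compare
from .synthetic import GeneratorConfig, GroundTruth, simulate_study


def benchmark_experiment(seed: int) -> tuple[BenchmarkResult, GroundTruth]:
    """The standard three-tissue study (blood + two others, four datasets
    each, 120 samples per dataset) benchmarked over the short ladder
    {25, 50, 75, 100, full} with elastic-net and lasso, plus the
    blood-to-tissue transfer."""
    study, truth = simulate_study(GeneratorConfig(seed=seed))
    plan = ExperimentPlan(
        penalties=(ELASTIC_NET, LASSO),
        ladder=(25, 50, 75, 100),
        include_transfer=True,
        seed=seed,
    )
    return run_full_benchmark(study, plan), truth


def sex_experiment(seed: int, planted: bool) -> BenchmarkResult:
    """The standard three-tissue study trained jointly and per sex, with the
    per-tissue sex contrasts BY-adjusted as one family (the reporting
    convention this pipeline follows throughout). ``planted=True`` adds
    sex-modulated clock CpGs whose drift slope differs between sexes by the
    same magnitude as the age signal."""
    cfg = GeneratorConfig(
        n_sex_modulated_cpgs=20 if planted else 0,
        seed=seed,
    )
    study, _ = simulate_study(cfg)
    plan = ExperimentPlan(
        penalties=(ELASTIC_NET,),
        sex_configs=("joint", "male", "female"),
        ladder=(25, 50),
        seed=seed,
    )
    return run_full_benchmark(study, plan)


def _validation(scores: pd.DataFrame) -> pd.DataFrame:
    return scores[scores["split"] == "validation"]


def size_effect_analysis(scores: pd.DataFrame) -> list[ComparisonResult]:
    """Score ~ log(sample size) + (1|GSE) on elastic-net clocks trained and
    validated jointly, pooled over tissues; family = {adjusted R2, RMSE}."""
    val = _validation(scores)
    rows = val[(val["penalty"] == "elastic_net") & (val["validation_sex"] == "joint")
               & (val["sex_config"] == "joint") & (val["tissue_specific"] == 1)]
    results = [compare(rows, MixedModelSpec("size", response=resp))
               for resp in ("adjusted_r2", "rmse")]
    return adjust_family(results)


def penalty_analysis(scores: pd.DataFrame) -> list[ComparisonResult]:
    """Per-tissue Score ~ log(n) + Penalty + (1|GSE) for the lasso vs
    elastic-net pair on adjusted R2; family = tissues."""
    val = _validation(scores)
    rows = val[(val["validation_sex"] == "joint") & (val["sex_config"] == "joint")
               & (val["tissue_specific"] == 1)]
    results = []
    for tissue in sorted(rows["tissue"].unique()):
        results.append(compare(
            rows[rows["tissue"] == tissue],
            MixedModelSpec("penalty", contrast=("elastic_net", "lasso")),
            tissue_label=tissue))
    return adjust_family(results)


def sex_analysis(scores: pd.DataFrame) -> list[ComparisonResult]:
    """Per-tissue Score ~ log(n) + Sex.specific + (1|GSE) on elastic-net
    clocks validated separately on males and females; family = tissues."""
    val = _validation(scores)
    rows = val[val["penalty"] == "elastic_net"]
    results = []
    for tissue in sorted(rows["tissue"].unique()):
        results.append(compare(rows[rows["tissue"] == tissue],
                               MixedModelSpec("sex_specific"),
                               tissue_label=tissue))
    return adjust_family(results)


def tissue_specific_analysis(
    scores: pd.DataFrame, blood_code: str = BLOOD_CODE
) -> list[ComparisonResult]:
    """Per non-blood tissue Score ~ log(n) + Tissue.specific + (1|GSE),
    pairing tissue-trained LODO clocks with the blood-trained transfer;
    family = tissues x {adjusted R2, RMSE}."""
    val = _validation(scores)
    rows = val[(val["penalty"] == "elastic_net") & (val["validation_sex"] == "joint")
               & (val["sex_config"] == "joint") & (val["tissue"] != blood_code)]
    results = []
    for tissue in sorted(rows["tissue"].unique()):
        sub = rows[rows["tissue"] == tissue]
        for resp in ("adjusted_r2", "rmse"):
            results.append(compare(
                sub, MixedModelSpec("tissue_specific", response=resp),
                tissue_label=tissue))
    return adjust_family(results)


def planted_recall(seed: int) -> float:
    """Recall of planted clock CpGs by a single elastic-net clock trained on
    200 samples with a sparse 10-CpG signal (slope 0.03) and noise SD 0.5."""
    from .clock import fit_clock
    from .preprocess import beta_to_m

    cfg = GeneratorConfig(
        tissues=(BLOOD_CODE,), datasets_per_tissue=2, samples_per_dataset=100,
        n_background_cpgs=200, n_shared_clock_cpgs=10,
        n_tissue_specific_clock_cpgs=0, slope_range=(0.03, 0.03),
        noise_sd=0.5, missing_rate=0.0, seed=seed)
    study, truth = simulate_study(cfg)
    M = beta_to_m(study.beta)
    ages = study.samples.set_index("sample_id")["age"]
    model = fit_clock(M, ages.loc[M.columns], ELASTIC_NET, seed=seed)
    planted = set(truth.shared_cpgs)
    return len(model.nonzero_cpgs() & planted) / len(planted)
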