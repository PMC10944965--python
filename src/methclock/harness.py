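"""Experimental design: leave-one-dataset-out validation, the age-stratified
subsampling ladder, sex configurations, and the blood-to-tissue transfer.

Within each tissue, every dataset (GSE) is iteratively held out: a clock is
trained on the remaining datasets pooled and validated on the held-out one,
for every (penalty, sex configuration, training-set size) cell of the plan.
A clock is only computed when both the training and the validation side have
at least three samples. Training sets are reduced to each ladder size by
age-stratified subsampling (decade bins; largest-remainder quotas); samples
excluded by subsampling form the test split. Finally, a clock trained on all
blood samples is evaluated on every other tissue's validation datasets to
quantify the advantage of tissue-specific training.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clock import ELASTIC_NET, ClockModel, PenaltySpec, fit_clock
from .errors import DegenerateDesignError, EmptySelectionError
from .evaluation import ScoreRecord, score_clock
from .io_formats import MethylationStudy
from .preprocess import EPSILON_DEFAULT, filter_samples, preprocess_pair

#: training-set sizes tried for each clock, plus the full training set
LADDER_DEFAULT = (25, 50, 75, 100, 125, 150, 175, 200, 300, 400, 500,
                  750, 1000, 1250, 1750, 2000, 2250, 2500, 2750)

#: decade age strata over (20, 85]: (20,30], (30,40], ..., (70,80], (80,85]
AGE_STRATA_EDGES = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

BLOOD_CODE = "A12.207.152"

_SEX_CODE = {"male": "M", "female": "F"}


@dataclass
class ExperimentPlan:
    """Everything that defines one benchmark run."""

    tissue_targets: tuple[str, ...] | None = None  # None: tissues in the data
    penalties: tuple[PenaltySpec, ...] = (ELASTIC_NET,)
    sex_configs: tuple[str, ...] = ("joint",)
    ladder: tuple[int, ...] = LADDER_DEFAULT
    min_samples: int = 3
    nlambda: int = 50
    seed: int = 0
    blacklist: frozenset[str] = frozenset()
    epsilon: float = EPSILON_DEFAULT
    include_transfer: bool = False
    transfer_penalties: tuple[PenaltySpec, ...] = (ELASTIC_NET,)
    blood_code: str = BLOOD_CODE
    alias_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.ladder) != sorted(set(self.ladder)):
            raise ValueError("ladder must be strictly increasing")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")


@dataclass
class BenchmarkResult:
    scores: pd.DataFrame
    models: dict[tuple, ClockModel]
    skipped: list[tuple]  # (cell description, reason)

    def records(self) -> pd.DataFrame:
        return self.scores


def cell_seed(master: int, *labels) -> int:
    """Deterministic per-cell seed: cells are independent and reproducible
    regardless of iteration order."""
    key = "|".join(str(x) for x in (master, *labels))
    digest = hashlib.blake2s(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


def aggregate_tissue(samples: pd.DataFrame, target_code: str,
                     alias_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Samples whose tissue code equals the target or has it as a
    dot-boundary prefix; the alias map first folds suffix-labeled codes
    (e.g. blood-cell subsets like ``A12.207.152.CD4``) into their parent."""
    codes = samples["tissue_code"].astype(str)
    if alias_map:
        codes = codes.map(lambda c: alias_map.get(c, c))
    hit = (codes == target_code) | codes.str.startswith(target_code + ".")
    return samples[hit]


def _stratum_index(ages: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.asarray(AGE_STRATA_EDGES), ages, side="left")


def stratified_subsample(samples: pd.DataFrame, size: int, seed: int):
    """Draw an age-stratified subsample of ``size`` samples.

    Per-stratum quotas are proportional to stratum size with
    largest-remainder rounding (ties broken by stratum order); the draw
    within each stratum is uniform without replacement. Returns
    ``(subsample_ids, excluded_ids)`` — a disjoint partition of the input.
    """
    n = samples.shape[0]
    if size > n:
        raise ValueError(f"subsample size {size} exceeds n={n}")
    ids = samples["sample_id"].to_numpy()
    strata = _stratum_index(samples["age"].to_numpy(dtype=float))
    labels, counts = np.unique(strata, return_counts=True)
    exact = size * counts / n
    quota = np.floor(exact).astype(int)
    frac = exact - quota
    # distribute the remainder to the largest fractional parts with capacity
    order = np.argsort(-frac, kind="stable")
    left = size - quota.sum()
    for idx in list(order) * 2:  # second pass if first-choice strata are full
        if left == 0:
            break
        if quota[idx] < counts[idx]:
            quota[idx] += 1
            left -= 1
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for lab, q in zip(labels, quota):
        members = ids[strata == lab]
        if q >= members.size:
            chosen.extend(members)
        elif q > 0:
            chosen.extend(rng.choice(members, size=q, replace=False))
    chosen_set = set(chosen)
    sub = [s for s in ids if s in chosen_set]
    excluded = [s for s in ids if s not in chosen_set]
    return sub, excluded


def _ladder_sizes(plan: ExperimentPlan, n_train: int) -> list[int]:
    sizes = [s for s in plan.ladder if s < n_train]  # "when available"
    sizes.append(n_train)  # the full training set is always the last rung
    return sizes


def _sex_subset(samples: pd.DataFrame, sex_config: str) -> pd.Series:
    if sex_config == "joint":
        return samples["sample_id"]
    return samples.loc[samples["sex"] == _SEX_CODE[sex_config], "sample_id"]


def leave_one_dataset_out(
    study: MethylationStudy,
    plan: ExperimentPlan,
    tissue: str,
) -> BenchmarkResult:
    """LODO validation of one tissue's pooled study.

    ``study`` must already be sample-filtered and restricted to the tissue.
    Emits validation records (per validation sex), a training-split record,
    and a test-split record whenever subsampling excluded samples.
    """
    gses = list(pd.unique(study.samples["gse_id"]))
    if len(gses) < 2:
        raise DegenerateDesignError(f"tissue {tissue}: need >= 2 datasets for LODO")

    records: list[ScoreRecord] = []
    models: dict[tuple, ClockModel] = {}
    skipped: list[tuple] = []
    ages = study.samples.set_index("sample_id")["age"]

    for gse_out in gses:
        val_ids = study.samples.loc[study.samples["gse_id"] == gse_out, "sample_id"]
        train_sheet = study.samples[study.samples["gse_id"] != gse_out]
        val_study = study.subset_samples(list(val_ids))
        train_study = study.subset_samples(list(train_sheet["sample_id"]))
        try:
            M_train, M_val, _ = preprocess_pair(
                train_study, val_study, plan.blacklist, plan.epsilon)
        except EmptySelectionError as exc:
            skipped.append(((tissue, gse_out), f"probe filtering: {exc}"))
            continue
        val_sheet = val_study.samples

        for sex_config in plan.sex_configs:
            pool_ids = list(_sex_subset(train_sheet, sex_config))
            if len(pool_ids) < plan.min_samples:
                skipped.append(((tissue, gse_out, sex_config), "training side < 3 samples"))
                continue
            val_sexes = (("joint", "male", "female") if sex_config == "joint"
                         else (sex_config,))
            val_id_sets = {vs: list(_sex_subset(val_sheet, vs)) for vs in val_sexes}
            if all(len(v) < plan.min_samples for v in val_id_sets.values()):
                skipped.append(((tissue, gse_out, sex_config), "validation side < 3 samples"))
                continue
            pool_sheet = train_sheet[train_sheet["sample_id"].isin(pool_ids)]

            for size in _ladder_sizes(plan, len(pool_ids)):
                for penalty in plan.penalties:
                    seed = cell_seed(plan.seed, tissue, gse_out, penalty.name,
                                     sex_config, size)
                    sub_ids, test_ids = stratified_subsample(pool_sheet, size, seed)
                    if len(sub_ids) < plan.min_samples:
                        skipped.append(((tissue, gse_out, sex_config, size, penalty.name),
                                        "subsample < 3 samples"))
                        continue
                    model = fit_clock(
                        M_train[sub_ids], ages.loc[sub_ids], penalty,
                        seed=seed, nlambda=plan.nlambda, tissue=tissue,
                        sex_config=sex_config,
                        training_gse_ids=sorted(set(pool_sheet["gse_id"])),
                        subsample_size=size,
                    )
                    models[(tissue, gse_out, penalty.name, sex_config, size)] = model
                    for val_sex, v_ids in val_id_sets.items():
                        rec = score_clock(
                            model, M_val[v_ids], ages.loc[v_ids],
                            split="validation", gse_id=gse_out, tissue=tissue,
                            validation_sex=val_sex,
                        ) if len(v_ids) >= plan.min_samples else None
                        if rec is None:
                            skipped.append(((tissue, gse_out, sex_config, size,
                                             penalty.name, val_sex), "validation subset < 3"))
                        else:
                            records.append(rec)
                    rec = score_clock(model, M_train[sub_ids], ages.loc[sub_ids],
                                      split="training", gse_id=gse_out, tissue=tissue,
                                      validation_sex=sex_config if sex_config != "joint" else "joint")
                    if rec is not None:
                        records.append(rec)
                    if len(test_ids) >= plan.min_samples:
                        rec = score_clock(model, M_train[test_ids], ages.loc[test_ids],
                                          split="test", gse_id=gse_out, tissue=tissue,
                                          validation_sex=sex_config if sex_config != "joint" else "joint")
                        if rec is not None:
                            records.append(rec)

    from .io_formats import scores_to_frame

    return BenchmarkResult(scores_to_frame(records), models, skipped)


def run_transfer(
    study: MethylationStudy,
    plan: ExperimentPlan,
    targets: Sequence[str],
) -> BenchmarkResult:
    """Train on all blood samples, validate on other tissues' datasets.

    Emits tissue_specific=False records, one per (penalty, target tissue,
    validation dataset); pair them with the tissue-trained (tissue_specific
    =True) LODO records for the mixed-model contrast.
    """
    blood_sheet = aggregate_tissue(study.samples, plan.blood_code, plan.alias_map)
    if blood_sheet.shape[0] < plan.min_samples:
        raise DegenerateDesignError("fewer than 3 blood samples to train on")
    other_targets = [t for t in targets if t != plan.blood_code]
    other_sheets = {t: aggregate_tissue(study.samples, t, plan.alias_map)
                    for t in other_targets}
    pool_ids = [s for t in other_targets for s in other_sheets[t]["sample_id"]]

    blood_study = study.subset_samples(list(blood_sheet["sample_id"]))
    other_study = study.subset_samples(pool_ids)
    M_blood, M_other, _ = preprocess_pair(
        blood_study, other_study, plan.blacklist, plan.epsilon)
    ages = study.samples.set_index("sample_id")["age"]

    records: list[ScoreRecord] = []
    models: dict[tuple, ClockModel] = {}
    skipped: list[tuple] = []
    n_blood = blood_sheet.shape[0]
    for penalty in plan.transfer_penalties:
        seed = cell_seed(plan.seed, "transfer", plan.blood_code, penalty.name)
        model = fit_clock(
            M_blood, ages.loc[M_blood.columns], penalty, seed=seed,
            nlambda=plan.nlambda, tissue=plan.blood_code, sex_config="joint",
            training_gse_ids=sorted(set(blood_sheet["gse_id"])),
            subsample_size=n_blood,
        )
        models[("transfer", penalty.name)] = model
        for target in other_targets:
            sheet = other_sheets[target]
            for gse in pd.unique(sheet["gse_id"]):
                v_ids = list(sheet.loc[sheet["gse_id"] == gse, "sample_id"])
                rec = score_clock(model, M_other[v_ids], ages.loc[v_ids],
                                  split="validation", gse_id=gse, tissue=target,
                                  validation_sex="joint", tissue_specific=False)
                if rec is None:
                    skipped.append((("transfer", target, gse, penalty.name),
                                    "validation dataset < 3"))
                else:
                    records.append(rec)

    from .io_formats import scores_to_frame

    return BenchmarkResult(scores_to_frame(records), models, skipped)


def run_full_benchmark(study: MethylationStudy, plan: ExperimentPlan) -> BenchmarkResult:
    """Sample-filter the study, then run LODO per tissue target and,
    optionally, the blood transfer. Deterministic under the plan seed."""
    filtered, _ = filter_samples(study, seed=plan.seed)
    targets = (plan.tissue_targets if plan.tissue_targets is not None
               else tuple(pd.unique(filtered.samples["tissue_code"])))

    all_scores: list[pd.DataFrame] = []
    models: dict[tuple, ClockModel] = {}
    skipped: list[tuple] = []
    for tissue in targets:
        sheet = aggregate_tissue(filtered.samples, tissue, plan.alias_map)
        if sheet.empty:
            skipped.append(((tissue,), "no samples for tissue target"))
            continue
        sub = filtered.subset_samples(list(sheet["sample_id"]))
        result = leave_one_dataset_out(sub, plan, tissue)
        all_scores.append(result.scores)
        models.update(result.models)
        skipped.extend(result.skipped)

    if plan.include_transfer:
        result = run_transfer(filtered, plan, list(targets))
        all_scores.append(result.scores)
        models.update(result.models)
        skipped.extend(result.skipped)

    scores = (pd.concat([s for s in all_scores if not s.empty], ignore_index=True)
              if any(not s.empty for s in all_scores) else pd.DataFrame())
    return BenchmarkResult(scores, models, skipped)
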