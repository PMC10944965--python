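"""Sample filters, probe filters, imputation and the beta -> M transform.

Pipeline order is impute -> (normalization hook) -> probe filters ->
logit2 transform. Normalization is an identity hook: reference-based
between-array normalization methods operate on real array data and are
pluggable here; synthetic studies do not need them.

Sample rules: keep controls with 20 < age <= 85 (boundaries: age 20 is
removed, age 85 kept) and, within each family (twins, repeated measures),
keep exactly one sample chosen uniformly at random under the run seed.

Probe rules (applied jointly to a training/validation pair): keep CpGs
present in both studies, then drop CpGs still carrying missing values after
imputation, blacklisted/unreliable probes, rs (SNP control) probes and
everything on the X and Y chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import BetaRangeError, EmptySelectionError
from .io_formats import MethylationStudy

EPSILON_DEFAULT = 1e-6

SAMPLE_RULES = ("age_low", "age_high", "non_control", "paired_duplicate")
PROBE_RULES = ("probe_not_shared", "probe_rs", "probe_xy",
               "probe_unreliable", "probe_missing")


@dataclass
class FilterReport:
    """Counts and ids removed per filtering rule.

    Probe counts are taken over the union of the two studies' probe sets, so
    the counts sum exactly to |union| - |retained|.
    """

    counts: dict[str, int] = field(default_factory=dict)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    seed: int | None = None

    def record(self, rule: str, ids) -> None:
        ids = sorted(ids)
        self.counts[rule] = self.counts.get(rule, 0) + len(ids)
        self.removed_ids.setdefault(rule, []).extend(ids)

    @property
    def total_removed(self) -> int:
        return sum(self.counts.values())


def filter_samples(study: MethylationStudy, seed: int = 0):
    """Apply the age-window, control-status and paired-sample rules.

    Returns ``(filtered_study, report)``; raises
    :class:`EmptySelectionError` naming the rule that emptied the study.
    """
    report = FilterReport(seed=seed)
    sheet = study.samples
    sid = sheet["sample_id"]

    age_low = sid[sheet["age"] <= 20]
    age_high = sid[sheet["age"] > 85]
    report.record("age_low", age_low)
    report.record("age_high", age_high)
    keep = sheet[(sheet["age"] > 20) & (sheet["age"] <= 85)]
    if keep.empty:
        raise EmptySelectionError("age window (20, 85] removed every sample")

    non_control = keep.loc[keep["status"] != "control", "sample_id"]
    report.record("non_control", non_control)
    keep = keep[keep["status"] == "control"]
    if keep.empty:
        raise EmptySelectionError("health-status filter removed every sample")

    # one sample per family, chosen uniformly at random
    rng = np.random.default_rng(seed)
    fam = keep["family_id"].fillna(keep["sample_id"])
    chosen: list[str] = []
    dropped: list[str] = []
    for _, members in keep.groupby(fam, sort=True)["sample_id"]:
        ids = list(members)
        pick = ids[rng.integers(len(ids))] if len(ids) > 1 else ids[0]
        chosen.append(pick)
        dropped.extend(i for i in ids if i != pick)
    report.record("paired_duplicate", dropped)

    keep_ids = [s for s in sheet["sample_id"] if s in set(chosen)]  # original order
    return study.subset_samples(keep_ids), report


def impute_missing(study: MethylationStudy) -> MethylationStudy:
    """Replace each missing beta by the mean of the probe's non-missing
    betas within the same dataset (gse_id). Probes entirely missing within a
    dataset stay missing and are caught by :func:`filter_probes`."""
    beta = study.beta.copy()
    for gse, members in study.samples.groupby("gse_id")["sample_id"]:
        cols = list(members)
        block = beta[cols]
        means = block.mean(axis=1)
        beta[cols] = block.mask(block.isna(), means, axis=0)
    return MethylationStudy(beta, study.samples.copy(), study.probes.copy())


def filter_probes(
    train: MethylationStudy,
    validation: MethylationStudy,
    blacklist: set[str] | frozenset[str] = frozenset(),
):
    """Joint probe filtering of a training/validation pair.

    Retains the intersection of probe sets minus rs probes, X/Y probes,
    blacklisted or unreliable probes, and probes with any remaining missing
    value; the retained set is returned in sorted order in both studies
    (set semantics: the result is invariant to input probe order).
    """
    report = FilterReport()
    ids_train = set(train.probes["cpg_id"])
    ids_val = set(validation.probes["cpg_id"])
    union = ids_train | ids_val
    shared = ids_train & ids_val
    report.record("probe_not_shared", union - shared)

    ann = train.probes.set_index("cpg_id").loc[sorted(shared)]
    rs = set(ann.index[ann["probe_class"] == "rs"])
    report.record("probe_rs", rs)
    pool = shared - rs
    xy = set(ann.index[ann["chromosome"].isin(["X", "Y"])]) & pool
    report.record("probe_xy", xy)
    pool -= xy
    unrel = (set(ann.index[ann["unreliable"].astype(bool)]) | set(blacklist)) & pool
    report.record("probe_unreliable", unrel)
    pool -= unrel

    def _has_missing(study: MethylationStudy, ids: set[str]) -> pd.Series:
        return study.beta.loc[sorted(ids)].isna().any(axis=1)

    miss_t = _has_missing(train, pool)
    miss_v = _has_missing(validation, pool)
    missing = set(miss_t.index[miss_t]) | set(miss_v.index[miss_v])
    report.record("probe_missing", missing)
    pool -= missing

    if not pool:
        raise EmptySelectionError("probe filtering removed every probe")
    order = sorted(pool)
    return train.subset_probes(order), validation.subset_probes(order), report


def beta_to_m(beta, epsilon: float = EPSILON_DEFAULT):
    """logit2 transform M = log2(beta / (1 - beta)).

    Betas are clamped to [epsilon, 1 - epsilon] first so the boundary values
    0 and 1 map to large finite M-values; anything outside [0, 1] raises.
    Vectorized: accepts scalars, arrays or DataFrames.
    """
    arr = np.asarray(beta, dtype=float)
    finite = ~np.isnan(arr)
    if ((arr[finite] < 0) | (arr[finite] > 1)).any():
        raise BetaRangeError("beta outside [0, 1]")
    clamped = np.clip(arr, epsilon, 1 - epsilon)
    m = np.log2(clamped / (1 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if np.isscalar(m):
        return float(out)
    return out


def identity_normalization(study: MethylationStudy) -> MethylationStudy:
    """Normalization hook: the default is a no-op; real-data users can plug
    in a reference-based method with the same signature."""
    return study


def preprocess_pair(
    train: MethylationStudy,
    validation: MethylationStudy,
    blacklist: set[str] = frozenset(),
    epsilon: float = EPSILON_DEFAULT,
    normalization: Callable[[MethylationStudy], MethylationStudy] = identity_normalization,
):
    """Full probe-side pipeline for a train/validation pair.

    impute -> normalize (hook) -> joint probe filters -> logit2. Returns
    ``(M_train, M_validation, report)`` where the M frames are probes x
    samples matrices ready for clock fitting.
    """
    train = normalization(impute_missing(train))
    validation = normalization(impute_missing(validation))
    train, validation, report = filter_probes(train, validation, blacklist)
    return beta_to_m(train.beta, epsilon), beta_to_m(validation.beta, epsilon), report
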