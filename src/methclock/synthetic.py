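"""Synthetic multi-dataset methylation studies with known ground truth.

Real age-clock benchmarks pool many public array datasets per tissue; this
generator emulates the statistical structure that pipeline assumes, with
every ingredient known exactly so recovery can be asserted:

* several datasets (GSE groups) per tissue, each with its own random
  intercept per CpG (batch effect), u ~ N(0, batch_sd^2);
* a minority of "clock" CpGs whose M-value drifts linearly with age —
  shared across tissues, tissue-specific, or sex-modulated (the drift slope
  differs between sexes) — against a background of CpGs with no age signal;
* Gaussian residual noise in M-space, uniform ages in (20, 85], balanced
  sexes, uniformly missing entries, and X/Y and rs control probes carrying
  no signal, for exercising the probe filters.

For clock CpG j in sample i of dataset g:

    M_ij = b_j + (s_j + delta_j * 1[sex_i = F]) * age_i + u_{j,g} + eps_ij

and beta = 2^M / (1 + 2^M). Baselines are clamped so beta stays inside
(0.01, 0.99) over the age range at +-3 total SD, avoiding logit saturation.
Each dataset has its own RNG stream derived from (seed, tissue, dataset),
so adding a dataset never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import ScoreRecord
from .io_formats import MethylationStudy, validate_study

M_SAFE = np.log2(0.99 / 0.01)  # |M| bound keeping beta in (0.01, 0.99)

#: MeSH-style codes used by the default study: blood, nervous, digestive.
DEFAULT_TISSUES = ("A12.207.152", "A08.186", "A03.556")


@dataclass
class GeneratorConfig:
    """Study-design and signal parameters of the generator.

    Defaults describe the study the package's own benchmark runs on: three
    tissues, four datasets each, 120 samples per dataset, a sparse linear
    age signal (slopes 0.01-0.05 M-units/year) over a null background,
    moderate batch effects and residual noise of 0.5 M-units.
    """

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    datasets_per_tissue: int = 4
    samples_per_dataset: int = 120
    age_range: tuple[float, float] = (20.0, 85.0)  # half-open (lo, hi]
    n_background_cpgs: int = 150
    n_shared_clock_cpgs: int = 20
    n_tissue_specific_clock_cpgs: int = 10
    n_sex_modulated_cpgs: int = 0
    slope_range: tuple[float, float] = (0.01, 0.05)  # M-units / year
    baseline_range: tuple[float, float] = (-2.0, 2.0)  # M-units
    batch_sd: float = 0.2  # SD of dataset-level intercepts, M-units
    noise_sd: float = 0.5  # residual SD, M-units
    missing_rate: float = 0.01
    n_xy_probes: int = 8
    n_rs_probes: int = 4
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        counts = (self.datasets_per_tissue, self.samples_per_dataset,
                  self.n_background_cpgs, self.n_shared_clock_cpgs,
                  self.n_tissue_specific_clock_cpgs, self.n_sex_modulated_cpgs,
                  self.n_xy_probes, self.n_rs_probes)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if len(self.tissues) == 0:
            raise ValueError("need at least one tissue")
        if self.datasets_per_tissue == 0:
            raise ValueError("need at least one dataset per tissue")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ValueError("SDs must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.age_range
        if not (0 < lo < hi <= 120):
            raise ValueError("age_range must lie within (0, 120)")
        return self


@dataclass
class GroundTruth:
    """Planted parameters of a simulated study."""

    shared_cpgs: list[str]
    tissue_specific_cpgs: dict[str, list[str]]  # tissue -> CpGs
    sex_modulated_cpgs: list[str]
    slopes: dict[str, float]  # cpg -> base slope (M-units / year)
    sex_deltas: dict[str, float]  # cpg -> added female slope
    baselines: dict[str, float]
    dataset_intercepts: pd.DataFrame  # gse x cpg

    def all_clock_cpgs(self) -> set[str]:
        out = set(self.shared_cpgs) | set(self.sex_modulated_cpgs)
        for cpgs in self.tissue_specific_cpgs.values():
            out |= set(cpgs)
        return out


def _clamped_baseline(rng, baseline_range, slopes_at_cpg, age_lo, age_hi, sigma_tot):
    """Draw a baseline keeping M within +-M_SAFE at +-3 sigma over the ages."""
    extremes = [s * a for s in slopes_at_cpg for a in (age_lo, age_hi)]
    lo_b = -M_SAFE + 3 * sigma_tot - min(extremes)
    hi_b = M_SAFE - 3 * sigma_tot - max(extremes)
    b = rng.uniform(*baseline_range)
    if lo_b > hi_b:  # slope too steep for any safe baseline: center it
        return 0.5 * (lo_b + hi_b)
    return float(np.clip(b, lo_b, hi_b))


def simulate_study(config: GeneratorConfig) -> tuple[MethylationStudy, GroundTruth]:
    """Generate a validated multi-tissue study and its ground truth.

    Deterministic: the same config (including seed) yields bit-identical
    output.
    """
    config.validate()
    tissues = list(config.tissues)
    age_lo, age_hi = config.age_range
    sigma_tot = float(np.hypot(config.batch_sd, config.noise_sd))
    rng_global = np.random.default_rng([config.seed, 0])

    # ---- probe universe -------------------------------------------------
    shared = [f"cg_shared_{i:04d}" for i in range(config.n_shared_clock_cpgs)]
    tissue_specific = {
        t: [f"cg_t{ti}_{i:04d}" for i in range(config.n_tissue_specific_clock_cpgs)]
        for ti, t in enumerate(tissues)
    }
    sexmod = [f"cg_sex_{i:04d}" for i in range(config.n_sex_modulated_cpgs)]
    background = [f"cg_bg_{i:05d}" for i in range(config.n_background_cpgs)]
    xy = [f"cg_xy_{i:04d}" for i in range(config.n_xy_probes)]
    rs = [f"rs_{i:04d}" for i in range(config.n_rs_probes)]
    clock_cpgs = shared + [c for t in tissues for c in tissue_specific[t]] + sexmod
    autosomal = clock_cpgs + background
    all_cpgs = autosomal + xy + rs

    slopes: dict[str, float] = {}
    sex_deltas: dict[str, float] = {}
    baselines: dict[str, float] = {}
    for cpg in clock_cpgs:
        mag = rng_global.uniform(*config.slope_range)
        slopes[cpg] = float(mag * rng_global.choice([-1.0, 1.0]))
    for cpg in sexmod:
        mag = rng_global.uniform(*config.slope_range)
        sex_deltas[cpg] = float(mag * rng_global.choice([-1.0, 1.0]))
    for cpg in all_cpgs:
        s = slopes.get(cpg, 0.0)
        branch = [s, s + sex_deltas.get(cpg, 0.0)]
        baselines[cpg] = _clamped_baseline(
            rng_global, config.baseline_range, branch, age_lo, age_hi, sigma_tot)

    # annotation: two clock CpGs share a gene now and then; some CpGs have
    # two gene symbols, background occasionally none
    genes = []
    for i, cpg in enumerate(all_cpgs):
        if cpg in rs:
            genes.append("")
        elif i % 7 == 3:
            genes.append(f"GENE{i // 2:04d};GENE{i // 2 + 1:04d}")
        elif i % 11 == 5:
            genes.append("")
        else:
            genes.append(f"GENE{i // 2:04d}")
    chroms = [str(1 + i % 22) for i in range(len(autosomal))]
    chroms += ["X" if i % 2 == 0 else "Y" for i in range(len(xy))]
    chroms += [str(1 + i % 22) for i in range(len(rs))]
    probes = pd.DataFrame({
        "cpg_id": all_cpgs,
        "chromosome": chroms,
        "gene_symbols": genes,
        "probe_class": ["rs" if c in rs else "cg" for c in all_cpgs],
        "unreliable": False,
    })

    # ---- per-dataset samples -------------------------------------------
    slope_vec_base = np.array([slopes.get(c, 0.0) for c in all_cpgs])
    delta_vec = np.array([sex_deltas.get(c, 0.0) for c in all_cpgs])
    base_vec = np.array([baselines[c] for c in all_cpgs])
    p = len(all_cpgs)

    sheet_rows = []
    beta_blocks = []
    intercept_rows = {}
    for ti, tissue in enumerate(tissues):
        # tissue-specific CpGs only drift in their own tissue
        mask = np.ones(p)
        for other, cpgs in tissue_specific.items():
            if other != tissue:
                idx = [all_cpgs.index(c) for c in cpgs]
                mask[idx] = 0.0
        slope_vec = slope_vec_base * mask
        dvec = delta_vec * mask
        for d in range(config.datasets_per_tissue):
            gse = f"GSE{(ti + 1) * 100 + d}"
            rng = np.random.default_rng([config.seed, 1 + ti, d])
            n = config.samples_per_dataset
            ages = age_hi - rng.uniform(0.0, age_hi - age_lo, size=n)  # (lo, hi]
            female = rng.integers(0, 2, size=n)  # 1 = F
            u = rng.normal(0.0, config.batch_sd, size=p)
            eps = rng.normal(0.0, config.noise_sd, size=(p, n))
            eff_slope = slope_vec[:, None] + dvec[:, None] * female[None, :]
            M = base_vec[:, None] + eff_slope * ages[None, :] + u[:, None] + eps
            beta = 1.0 / (1.0 + np.exp2(-M))
            if config.missing_rate > 0:
                miss = rng.random(size=(p, n)) < config.missing_rate
                beta = np.where(miss, np.nan, beta)
            sample_ids = [f"S{gse}_{i:03d}" for i in range(n)]
            beta_blocks.append(pd.DataFrame(beta, index=all_cpgs, columns=sample_ids))
            intercept_rows[gse] = u
            for i in range(n):
                sheet_rows.append({
                    "sample_id": sample_ids[i], "gse_id": gse,
                    "age": float(ages[i]), "sex": "F" if female[i] else "M",
                    "tissue_code": tissue, "status": "control",
                    "family_id": sample_ids[i],
                })

    samples = pd.DataFrame(sheet_rows)
    beta = pd.concat(beta_blocks, axis=1)
    beta.index.name = "cpg_id"
    study = MethylationStudy(beta=beta, samples=samples, probes=probes)
    validate_study(study)
    truth = GroundTruth(
        shared_cpgs=shared,
        tissue_specific_cpgs=tissue_specific,
        sex_modulated_cpgs=sexmod,
        slopes=slopes,
        sex_deltas=sex_deltas,
        baselines=baselines,
        dataset_intercepts=pd.DataFrame(intercept_rows, index=all_cpgs).T,
    )
    return study, truth


# ---------------------------------------------------------------------------
# direct score-table generator for mixed-model testing


SIZE_CHOICES = (25, 50, 75, 100, 150, 200, 300, 500)


def simulate_score_table(
    n_gse: int,
    effect: float,
    group_sd: float,
    resid_sd: float,
    seed: int = 0,
    n_per_group: int = 10,
) -> list[ScoreRecord]:
    """Generate a balanced score table with a known fixed effect.

    Score = effect * z + a_g + e with a_g ~ N(0, group_sd^2),
    e ~ N(0, resid_sd^2), where z is the within-table z-scored log sample
    size. The simulated score is written into ``adjusted_r2`` (arbitrary
    scale; ``rmse`` is set to 0); penalty / sex / tissue-specific labels are
    assigned uniformly at random, so every label contrast is null by
    construction — exactly what calibration tests need.
    """
    if n_gse < 2:
        raise ValueError("need at least 2 GSE groups")
    rng = np.random.default_rng(seed)
    sizes = rng.choice(SIZE_CHOICES, size=n_gse * n_per_group)
    logn = np.log(sizes.astype(float))
    z = (logn - logn.mean()) / logn.std(ddof=1)
    a = np.repeat(rng.normal(0.0, group_sd, size=n_gse), n_per_group)
    e = rng.normal(0.0, resid_sd, size=n_gse * n_per_group)
    score = effect * z + a + e
    penalties = rng.choice(["elastic_net", "lasso", "ridge"], size=score.size)
    sex_cfg = rng.choice(["joint", "male", "female"], size=score.size)
    val_sex = rng.choice(["male", "female"], size=score.size)
    tspec = rng.integers(0, 2, size=score.size)
    records = []
    for i in range(score.size):
        records.append(ScoreRecord(
            adjusted_r2=float(score[i]), rmse=0.0, split="validation",
            n=int(sizes[i]), gse_id=f"G{i // n_per_group:03d}", tissue="SYN",
            penalty=str(penalties[i]), sex_config=str(sex_cfg[i]),
            validation_sex=str(val_sex[i]), subsample_size=int(sizes[i]),
            tissue_specific=bool(tspec[i]),
        ))
    return records
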