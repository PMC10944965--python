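"""Readers and writers for every table the pipeline touches.

All tables are tab-separated UTF-8 text with '.' decimals and ``NA`` for
missing beta values; the first matrix column is ``cpg_id``. Sample order is
authoritative from the sample sheet: the beta matrix is reordered to match it
on read, which removes silent misalignment between matrix and metadata.

The central in-memory container is :class:`MethylationStudy` — a probes x
samples beta matrix plus a sample sheet and a probe annotation — which every
downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clock import ClockModel, PenaltySpec
from .errors import (
    BetaRangeError,
    DimensionMismatchError,
    DuplicateIdError,
    UnknownCodeError,
    ValidationError,
)
from .evaluation import ScoreRecord

SEXES = ("F", "M")
STATUSES = ("control", "case")
PROBE_CLASSES = ("cg", "rs", "ch")

SHEET_COLUMNS = ["sample_id", "gse_id", "age", "sex", "tissue_code", "status", "family_id"]
ANNOTATION_COLUMNS = ["cpg_id", "chromosome", "gene_symbols", "probe_class", "unreliable"]

#: Fixed column order of the long-format score table.
SCORE_COLUMNS = [
    "adjusted_r2", "rmse", "split", "n", "gse_id", "tissue", "penalty",
    "sex_config", "validation_sex", "subsample_size", "tissue_specific",
]

COMPARISON_COLUMNS = [
    "formula_id", "response", "contrast", "tissue", "partial_corr", "se",
    "t_statistic", "df", "p_value", "p_by", "group_var", "resid_var",
    "n_obs", "n_groups",
]


@dataclass
class MethylationStudy:
    """A beta-value matrix with aligned sample and probe metadata.

    Attributes
    ----------
    beta
        probes x samples DataFrame of methylation proportions in [0, 1];
        ``NaN`` marks missing values. Index = cpg_id, columns = sample_id.
    samples
        Sample sheet, one row per sample (columns: sample_id, gse_id, age,
        sex, tissue_code, status, family_id).
    probes
        Probe annotation, one row per CpG (columns: cpg_id, chromosome,
        gene_symbols, probe_class, unreliable).
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_probes(self) -> int:
        return self.probes.shape[0]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationStudy":
        """Return a study restricted to ``sample_ids`` (in the given order)."""
        keep = list(sample_ids)
        samples = self.samples.set_index("sample_id").loc[keep].reset_index()
        return MethylationStudy(self.beta[keep].copy(), samples, self.probes.copy())

    def subset_probes(self, cpg_ids: Sequence[str]) -> "MethylationStudy":
        """Return a study restricted to ``cpg_ids`` (in the given order)."""
        keep = list(cpg_ids)
        probes = self.probes.set_index("cpg_id").loc[keep].reset_index()
        return MethylationStudy(self.beta.loc[keep].copy(), self.samples.copy(), probes)

    def validate(self) -> "MethylationStudy":
        validate_study(self)
        return self


def validate_sample_sheet(samples: pd.DataFrame) -> None:
    missing = [c for c in SHEET_COLUMNS[:-1] if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample sheet lacks columns: {missing}")
    ids = samples["sample_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise DuplicateIdError(f"duplicated sample_id values: {dupes}")
    if not (samples["age"] > 0).all():
        raise ValidationError("ages must be positive")
    bad_sex = set(samples["sex"]) - set(SEXES)
    if bad_sex:
        raise UnknownCodeError(f"unknown sex codes: {sorted(bad_sex)}")
    bad_status = set(samples["status"]) - set(STATUSES)
    if bad_status:
        raise UnknownCodeError(f"unknown status codes: {sorted(bad_status)}")
    if (samples["tissue_code"].astype(str).str.len() == 0).any():
        raise ValidationError("tissue_code must be non-empty")


def validate_annotation(probes: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in probes.columns]
    if missing:
        raise ValidationError(f"probe annotation lacks columns: {missing}")
    ids = probes["cpg_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise DuplicateIdError(f"duplicated cpg_id values: {dupes}")
    bad = set(probes["probe_class"]) - set(PROBE_CLASSES)
    if bad:
        raise UnknownCodeError(f"unknown probe classes: {sorted(bad)}")


def validate_study(study: MethylationStudy) -> None:
    validate_sample_sheet(study.samples)
    validate_annotation(study.probes)
    beta = study.beta
    if beta.shape != (study.n_probes, study.n_samples):
        raise DimensionMismatchError(
            f"beta shape {beta.shape} != (probes={study.n_probes}, samples={study.n_samples})"
        )
    if list(beta.columns) != list(study.samples["sample_id"]):
        raise DimensionMismatchError("beta columns do not match sample sheet order")
    if list(beta.index) != list(study.probes["cpg_id"]):
        raise DimensionMismatchError("beta rows do not match annotation order")
    vals = beta.to_numpy(dtype=float)
    finite = ~np.isnan(vals)
    if finite.any() and ((vals[finite] < 0) | (vals[finite] > 1)).any():
        raise BetaRangeError("beta values outside [0, 1]")


# ---------------------------------------------------------------------------
# study I/O


def read_study(matrix_path, sheet_path, annotation_path) -> MethylationStudy:
    """Read and validate a study from three TSV files.

    The matrix is reordered so its columns follow the sample sheet and its
    rows follow the annotation. Raises the specific validation error for each
    documented malformed case.
    """
    samples = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str, "gse_id": str,
                                                       "tissue_code": str, "family_id": str})
    if "family_id" not in samples.columns:
        # absent family_id: every sample is its own family
        samples["family_id"] = samples.get("sample_id", pd.Series(dtype=str))
    samples["family_id"] = samples["family_id"].fillna(samples["sample_id"])
    probes = pd.read_csv(annotation_path, sep="\t", dtype={"cpg_id": str, "chromosome": str})
    if "gene_symbols" in probes.columns:
        probes["gene_symbols"] = probes["gene_symbols"].fillna("")
    if "unreliable" in probes.columns:
        probes["unreliable"] = probes["unreliable"].astype(bool)
    beta = pd.read_csv(matrix_path, sep="\t", na_values=["NA"], index_col=0)
    beta.index = beta.index.astype(str)

    validate_sample_sheet(samples)
    validate_annotation(probes)

    want_samples = list(samples["sample_id"])
    want_probes = list(probes["cpg_id"])
    missing_cols = set(want_samples) - set(beta.columns)
    missing_rows = set(want_probes) - set(beta.index)
    if missing_cols or missing_rows or beta.shape != (len(want_probes), len(want_samples)):
        raise DimensionMismatchError(
            f"matrix {beta.shape} does not cover sheet ({len(want_samples)} samples) "
            f"and annotation ({len(want_probes)} probes)"
        )
    beta = beta.loc[want_probes, want_samples].astype(float)
    study = MethylationStudy(beta, samples, probes)
    validate_study(study)
    return study


def write_study(study: MethylationStudy, matrix_path, sheet_path, annotation_path) -> None:
    """Write a study as the three TSVs that :func:`read_study` consumes."""
    out = study.beta.copy()
    out.index.name = "cpg_id"
    out.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%.17g")
    study.samples.to_csv(sheet_path, sep="\t", index=False)
    study.probes.to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clock model I/O

_META_PREFIX = "#"


def write_clock(model: ClockModel, path) -> Path:
    """Serialize a clock as a key-value metadata block plus a two-column
    cpg_id -> coefficient table holding only non-zero entries.

    ``read_clock(write_clock(m))`` reproduces ``m`` to 1e-12.
    """
    coefs = {k: v for k, v in model.coefficients.items() if v != 0.0}
    values = [model.intercept, *coefs.values()]
    if not np.all(np.isfinite(values)):
        raise ValidationError("clock has non-finite intercept or coefficients")
    meta = {
        "penalty": model.penalty.name,
        "alpha": repr(model.penalty.alpha),
        "lambda_selected": repr(model.lambda_selected),
        "intercept": repr(model.intercept),
        "tissue": model.tissue,
        "sex_config": model.sex_config,
        "n_train": str(model.n_train),
        "training_gse_ids": ",".join(model.training_gse_ids),
        "subsample_size": str(model.subsample_size),
        "seed": str(model.seed),
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"{_META_PREFIX} {key}={value}\n")
        fh.write("cpg_id\tcoefficient\n")
        for cpg, w in coefs.items():
            fh.write(f"{cpg}\t{w!r}\n")
    return path


def read_clock(path) -> ClockModel:
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith(_META_PREFIX):
            key, _, value = line[len(_META_PREFIX):].strip().partition("=")
            meta[key] = value
        else:
            body.append(line)
    if not body or body[0].split("\t") != ["cpg_id", "coefficient"]:
        raise ValidationError(f"malformed clock file {path}")
    for line in body[1:]:
        if not line:
            continue
        cpg, w = line.split("\t")
        rows.append((cpg, float(w)))
    penalty = PenaltySpec(name=meta["penalty"], alpha=float(meta["alpha"]))
    gses = tuple(g for g in meta.get("training_gse_ids", "").split(",") if g)
    return ClockModel(
        intercept=float(meta["intercept"]),
        coefficients=dict(rows),
        penalty=penalty,
        lambda_selected=float(meta["lambda_selected"]),
        tissue=meta.get("tissue", ""),
        sex_config=meta.get("sex_config", "joint"),
        n_train=int(meta.get("n_train", 0)),
        training_gse_ids=gses,
        subsample_size=int(meta.get("subsample_size", 0)),
        seed=int(meta.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# score and comparison tables


def scores_to_frame(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    rows = [r.as_dict() for r in records]
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_scores(records: Sequence[ScoreRecord], path) -> Path:
    """Write one row per ScoreRecord in the fixed SCORE_COLUMNS order."""
    records = list(records)
    if not records:
        raise ValidationError("refusing to write an empty score table")
    frame = scores_to_frame(records)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_scores(path) -> list[ScoreRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"gse_id": str, "tissue": str})
    if (frame["rmse"] < 0).any():
        raise ValidationError("negative rmse in score table")
    records = []
    for row in frame.itertuples(index=False):
        records.append(ScoreRecord(
            adjusted_r2=float(row.adjusted_r2), rmse=float(row.rmse),
            split=str(row.split), n=int(row.n), gse_id=str(row.gse_id),
            tissue=str(row.tissue), penalty=str(row.penalty),
            sex_config=str(row.sex_config), validation_sex=str(row.validation_sex),
            subsample_size=int(row.subsample_size),
            tissue_specific=bool(row.tissue_specific),
        ))
    return records


def write_comparisons(frame: pd.DataFrame, path) -> Path:
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return Path(path)
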