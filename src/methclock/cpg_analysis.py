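"""Which CpGs (and genes) do the clocks select?

Per tissue, the non-zero coefficients of every trained clock form a
clocks x CpGs matrix. Small coefficients (|c| <= 0.1, on the standardized-
predictor scale by default, where the cut is comparable across CpGs) are
zeroed, unstable CpGs — non-zero in less than 10% of the tissue's clocks —
are dropped, and the remaining selections are summarized as the
"all clocks" (intersection) and "any clock" (union) consensus sets, mapped
to gene symbols, counted over the seven regions of a three-set Venn
diagram, and compared against published clocks' gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clock import ClockModel
from .errors import MissingProbeError

COEF_CUT_DEFAULT = 0.1
MIN_FRAC_DEFAULT = 0.10


@dataclass
class SelectionProfile:
    """Coefficient matrix of one tissue's clocks (zeros included).

    Rows are clock ids, columns cpg_ids.
    """

    tissue: str
    coefficients: pd.DataFrame

    def __post_init__(self):
        if self.coefficients.index.duplicated().any():
            raise ValueError("clock ids must be unique")

    @property
    def n_clocks(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class OverlapCounts:
    """Counts of the 7 regions of a labeled three-set Venn diagram."""

    labels: tuple[str, str, str]
    only_a: int
    only_b: int
    only_c: int
    ab: int  # in A and B, not C
    ac: int
    bc: int
    abc: int

    @property
    def union_size(self) -> int:
        return (self.only_a + self.only_b + self.only_c
                + self.ab + self.ac + self.bc + self.abc)


def build_selection_profile(
    models: Mapping[str, ClockModel] | Sequence[tuple[str, ClockModel]],
    tissue: str,
    scale: str = "standardized",
) -> SelectionProfile:
    """Assemble a clocks x CpGs coefficient matrix from trained clocks.

    ``scale`` picks standardized-predictor coefficients (default; the 0.1
    threshold is meaningful across CpGs there) or original-scale ones.
    """
    if scale not in ("standardized", "original"):
        raise ValueError("scale must be 'standardized' or 'original'")
    items = list(models.items()) if isinstance(models, Mapping) else list(models)
    rows = {}
    for clock_id, model in items:
        coefs = model.coefficients_std if scale == "standardized" else model.coefficients
        if scale == "standardized" and not coefs and model.coefficients:
            raise ValueError(f"clock {clock_id} lacks standardized coefficients")
        rows[str(clock_id)] = coefs
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    frame = frame.reindex(sorted(frame.columns), axis=1)
    return SelectionProfile(tissue=tissue, coefficients=frame)


def threshold_coefficients(profile: SelectionProfile,
                           cut: float = COEF_CUT_DEFAULT) -> SelectionProfile:
    """Zero every coefficient with |c| <= cut (closed interval: a value
    exactly at the cut is zeroed)."""
    if cut < 0:
        raise ValueError("cut must be >= 0")
    coefs = profile.coefficients.where(profile.coefficients.abs() > cut, 0.0)
    return SelectionProfile(tissue=profile.tissue, coefficients=coefs)


def stability_filter(profile: SelectionProfile,
                     min_frac: float = MIN_FRAC_DEFAULT) -> SelectionProfile:
    """Drop CpG columns non-zero in less than ``min_frac`` of the clocks
    (a CpG at exactly the fraction is kept)."""
    if profile.n_clocks < 1:
        raise ValueError("profile has no clocks")
    frac = (profile.coefficients != 0.0).mean(axis=0)
    keep = frac.index[frac >= min_frac]
    return SelectionProfile(tissue=profile.tissue,
                            coefficients=profile.coefficients[list(keep)])


def consensus_sets(profile: SelectionProfile) -> tuple[set[str], set[str]]:
    """(all_clocks, any_clock): CpGs selected by every clock / by at least
    one clock."""
    nz = profile.coefficients != 0.0
    all_clocks = set(nz.columns[nz.all(axis=0)]) if profile.n_clocks else set()
    any_clock = set(nz.columns[nz.any(axis=0)])
    return all_clocks, any_clock


def map_to_genes(cpgs: Iterable[str], annotation: pd.DataFrame) -> set[str]:
    """Union of gene symbols over the CpGs; unannotated (empty) entries
    contribute nothing. Unknown cpg_ids raise."""
    cpgs = set(cpgs)
    ann = annotation.set_index("cpg_id")["gene_symbols"]
    unknown = cpgs - set(ann.index)
    if unknown:
        raise MissingProbeError(f"cpg ids missing from annotation: {sorted(unknown)}")
    genes: set[str] = set()
    for cpg in cpgs:
        field = ann.loc[cpg]
        symbols = field if isinstance(field, (list, tuple)) else str(field).split(";")
        genes |= {s.strip() for s in symbols if s and s.strip()}
    return genes


def overlap_counts(set_a: set, set_b: set, set_c: set,
                   labels: tuple[str, str, str] = ("A", "B", "C")) -> OverlapCounts:
    """Inclusion-exclusion counts of all 7 Venn regions."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    return OverlapCounts(
        labels=labels,
        only_a=len(a - b - c), only_b=len(b - a - c), only_c=len(c - a - b),
        ab=len((a & b) - c), ac=len((a & c) - b), bc=len((b & c) - a),
        abc=len(abc),
    )


def compare_to_reference_clocks(genes: Iterable[str],
                                reference: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """For each gene, which reference clocks also use it (case-insensitive
    symbol match). Returns a two-column frame: gene, clocks (';'-joined)."""
    if not reference:
        raise ValueError("reference clock map is empty")
    lowered = {name: {str(g).lower() for g in gs} for name, gs in reference.items()}
    rows = []
    for gene in sorted(set(genes)):
        hits = sorted(name for name, gs in lowered.items() if str(gene).lower() in gs)
        rows.append({"gene": gene, "clocks": ";".join(hits)})
    return pd.DataFrame(rows, columns=["gene", "clocks"])


def read_reference_gene_lists(path) -> dict[str, set[str]]:
    """Read a two-column TSV (clock_name, gene) into a clock -> genes map."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row[0]), set()).add(str(row[1]))
    return out
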