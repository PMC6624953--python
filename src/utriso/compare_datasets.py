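"""Cross-dataset comparison of per-gene, per-rank 3'UTR isoform annotations.

Because end positions carry up to 200 nt of uncertainty between two
annotations, a same-rank isoform is "conserved" between two datasets when its
lengths differ by less than 200 nt (strict).  With the full 2 sexes x 2
experimental series design, per-rank records receive a summary flag:

    ROBUST   conserved in all pairwise comparisons of the 4 datasets
    SEX-SPE  conserved within each sex across series, NOT conserved between
             sexes within either series (putative sex-specific isoform)
    EXP-SPE  conserved between sexes within each series, NOT conserved within
             either sex across series (experiment-specific isoform)

SEX-SPE and EXP-SPE are mutually exclusive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

CONSERVATION_WINDOW_NT = 200


@dataclass(frozen=True)
class DatasetLabel:
    name: str
    sex: str  # male | female
    series: str  # experiment series, e.g. "2014"


def _check_labels(labels: Sequence[DatasetLabel]) -> None:
    pairs = [(l.sex, l.series) for l in labels]
    if len(set(pairs)) != len(pairs):
        raise ValueError("(sex, series) pairs must be unique across datasets")


def pairwise_conserved(
    len_a: float | None, len_b: float | None, window: int = CONSERVATION_WINDOW_NT
) -> bool:
    """True when both lengths are present and differ by less than ``window`` nt."""
    if len_a is None or len_b is None:
        return False
    return abs(len_a - len_b) < window


def summary_flags(
    lengths: Mapping[str, float | None],
    labels: Sequence[DatasetLabel],
    window: int = CONSERVATION_WINDOW_NT,
    convention: str = "main_text",
) -> str:
    """Summary conservation flag for one (gene, rank) record across 4 datasets.

    ``lengths`` maps dataset name -> isoform length (or None when absent).
    Requires exactly 2 sexes x 2 series.  ``convention="swapped"`` exchanges
    the SEX-SPE / EXP-SPE labels (an alternative reading of the definitions).
    """
    _check_labels(labels)
    if len(labels) != 4 or len({l.sex for l in labels}) != 2 or len(
        {l.series for l in labels}
    ) != 2:
        raise ValueError("summary flags require 2 sexes x 2 experimental series")

    def conserved(a: DatasetLabel, b: DatasetLabel) -> bool:
        return pairwise_conserved(lengths.get(a.name), lengths.get(b.name), window)

    pairs = list(combinations(labels, 2))
    same_sex = [conserved(a, b) for a, b in pairs if a.sex == b.sex]
    cross_sex_within = [
        conserved(a, b) for a, b in pairs if a.sex != b.sex and a.series == b.series
    ]
    if all(conserved(a, b) for a, b in pairs):
        return "ROBUST"
    sex_spe = all(same_sex) and not any(cross_sex_within)
    exp_spe = all(cross_sex_within) and not any(same_sex)
    if convention == "swapped":
        sex_spe, exp_spe = exp_spe, sex_spe
    if sex_spe:
        return "SEX-SPE"
    if exp_spe:
        return "EXP-SPE"
    return "none"


def rank_label(rank: int) -> str:
    """Positional rank label used for cross-dataset alignment."""
    return "s/pUTR" if rank == 1 else f"dUTR{rank - 1}"


def conservation_table(
    catalogs: Mapping[str, pd.DataFrame],
    labels: Sequence[DatasetLabel] | None = None,
    window: int = CONSERVATION_WINDOW_NT,
    convention: str = "main_text",
) -> pd.DataFrame:
    """Align per-gene, per-rank isoform lengths across datasets and flag them.

    ``catalogs`` maps dataset name -> DataFrame with at least ``gene_id``,
    ``rank`` and ``length`` columns.  Rank alignment is positional (rank 1
    with rank 1, etc.).  Pairwise conserved columns are emitted for every
    dataset pair; summary flags only when 4 labelled datasets are given.
    """
    names = list(catalogs)
    per_ds: dict[str, dict[tuple[str, int], float]] = {}
    very_short: dict[tuple[str, int], bool] = {}
    for name, df in catalogs.items():
        d: dict[tuple[str, int], float] = {}
        for row in df.itertuples(index=False):
            key = (row.gene_id, int(row.rank))
            d[key] = float(row.length)
            if getattr(row, "very_short", False):
                very_short[key] = True
        per_ds[name] = d

    keys = sorted({k for d in per_ds.values() for k in d})
    do_summary = labels is not None and len(labels) == 4
    records = []
    for gene_id, rank in keys:
        lengths = {name: per_ds[name].get((gene_id, rank)) for name in names}
        rec: dict = {"gene_id": gene_id, "rank": rank, "utr_rank": rank_label(rank)}
        for name in names:
            rec[f"length_{name}"] = lengths[name]
        for a, b in combinations(names, 2):
            la, lb = lengths[a], lengths[b]
            rec[f"dlen_{a}_vs_{b}"] = (
                abs(la - lb) if la is not None and lb is not None else None
            )
            rec[f"conserved_{a}_vs_{b}"] = pairwise_conserved(la, lb, window)
        if do_summary:
            rec["flag"] = summary_flags(lengths, labels, window, convention)
        rec["very_short"] = very_short.get((gene_id, rank), False)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def common_genes(catalogs: Mapping[str, Iterable[str]]) -> dict:
    """Set intersections and Venn-partition tallies of annotated gene ids.

    Returns the genes common to all datasets, per-pair overlap counts and the
    full Venn partition (membership pattern -> count); partition counts sum to
    the union size.
    """
    sets = {name: set(genes) for name, genes in catalogs.items()}
    names = list(sets)
    union: set[str] = set().union(*sets.values()) if sets else set()
    common = set.intersection(*sets.values()) if sets else set()

    pair_counts = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    venn: dict[tuple[str, ...], int] = {}
    for g in union:
        pattern = tuple(name for name in names if g in sets[name])
        venn[pattern] = venn.get(pattern, 0) + 1
    return {
        "names": names,
        "common": sorted(common),
        "n_common": len(common),
        "union_size": len(union),
        "pair_counts": pair_counts,
        "venn": venn,
    }
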