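"""Relative abundance of 3'UTR isoforms and quantitative profile classes.

Nested 3'UTR isoforms tile the region after the stop codon into segments
bounded by adjacent 3' ends.  Because every isoform ending at or beyond a
segment covers it, the mean depth of segment i equals the summed abundance of
isoforms i..n; subtracting adjacent segment means therefore recovers each
isoform's abundance:

    RA_i = (d_i - d_{i+1}) / d_1   (i < n),      RA_n = d_n / d_1

where d_i is the mean depth of segment i (cumulative counts at its end minus
at its start, over its length).  Noise can invert adjacent means; negative raw
values are clamped to zero and the vector renormalized to sum 1 (raw values
are kept alongside).

Genes are then classified into quantitative profiles:

    P1  single isoform (no APA)
    P2  proximal isoform > 80% of the mRNA pool
    P3  proximal <= 80% and distal ranks >= 2 sum to < 10%
    P4  proximal <= 80% and distal ranks >= 2 sum to >= 10%
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np

from .isoform_catalog import MAX_ISOFORMS_IN_STATS, PolyASite, UtrIsoform

P2_PROXIMAL_MIN = 0.80  # strict: RA1 must exceed this for P2
P3_DISTAL_MAX = 0.10  # strict: distal sum must stay below this for P3


@dataclass(frozen=True)
class SegmentDepth:
    """Mean depth of the UTR segment between two adjacent 3' ends."""

    index: int  # 1..n
    start: int  # utr_pos, half-open [start, end); segment 1 starts at 1
    end: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneApaProfile:
    gene_id: str
    n_isoforms: int
    raw_abundance: tuple[float, ...]
    abundance: tuple[float, ...]  # clamped + renormalized, sums to 1
    profile: str  # P1..P4


def segment_depths(
    utr_coverage: np.ndarray,
    sites: Sequence[PolyASite] | Sequence[int],
    gene_id: str = "",
) -> list[SegmentDepth]:
    """Mean depth per inter-end segment from cumulative UTR coverage.

    ``sites`` may be merged polyA sites or plain representative end positions
    (sorted, strictly increasing, in nt after stop).
    """
    ends = [s.representative_end if isinstance(s, PolyASite) else int(s) for s in sites]
    if not ends:
        return []
    if sorted(set(ends)) != ends or ends[0] < 1:
        raise ValueError(f"{gene_id}: ends must be strictly increasing and >= 1")
    v = np.asarray(utr_coverage, dtype=float)
    if len(v) < ends[-1]:
        v = np.concatenate([v, np.zeros(ends[-1] - len(v))])
    cum = np.concatenate(([0.0], np.cumsum(v)))
    out: list[SegmentDepth] = []
    prev = 0
    for i, e in enumerate(ends, start=1):
        out.append(
            SegmentDepth(index=i, start=prev + 1, end=e + 1,
                         mean_depth=float(cum[e] - cum[prev]) / (e - prev))
        )
        prev = e
    return out


def relative_abundance(
    depths: Sequence[SegmentDepth] | Sequence[float],
) -> tuple[list[float], list[float]]:
    """Per-isoform relative abundance by segment subtraction.

    Returns ``(raw, normalized)``: raw values follow the subtraction formula
    and may be negative under noise; the normalized vector is clamped to
    [0, inf) and rescaled to sum 1.  Raises if the proximal segment is empty
    (gene unquantifiable).
    """
    d = [x.mean_depth if isinstance(x, SegmentDepth) else float(x) for x in depths]
    if not d:
        raise ValueError("no segments")
    if d[0] <= 0:
        raise ValueError("proximal segment has zero coverage: gene unquantifiable")
    raw = [(d[i] - d[i + 1]) / d[0] for i in range(len(d) - 1)]
    raw.append(d[-1] / d[0])
    clamped = [max(0.0, x) for x in raw]
    total = sum(clamped)
    if total == 0:
        raise ValueError("all abundances zero after clamping")
    return raw, [x / total for x in clamped]


def classify_profile(abundance: Sequence[float]) -> str:
    """Map a normalized abundance vector to its quantitative profile P1-P4.

    Boundaries are strict: RA1 = 0.80 exactly is not P2; a distal sum of 0.10
    exactly is P4, not P3.
    """
    if len(abundance) == 1:
        return "P1"
    if abundance[0] > P2_PROXIMAL_MIN:
        return "P2"
    if sum(abundance[2:]) < P3_DISTAL_MAX:
        return "P3"
    return "P4"


def quantify_gene(
    utr_coverage: np.ndarray,
    sites: Sequence[PolyASite],
    gene_id: str = "",
) -> GeneApaProfile:
    """segment_depths -> relative_abundance -> classify_profile for one gene."""
    d = segment_depths(utr_coverage, sites, gene_id=gene_id)
    raw, norm = relative_abundance(d)
    return GeneApaProfile(
        gene_id=gene_id,
        n_isoforms=len(norm),
        raw_abundance=tuple(raw),
        abundance=tuple(norm),
        profile=classify_profile(norm),
    )


def length_stats(catalogs: Sequence[Sequence[UtrIsoform]]) -> dict:
    """Summary length/count statistics over per-gene isoform catalogs.

    Restricted to genes with at most 5 isoforms.  Reports median lengths of
    the sUTR / pUTR / dUTR groups, the median per-gene dUTR1/pUTR length
    ratio, the isoform-count distribution and the APA fraction.
    """
    kept = [c for c in catalogs if c and len(c) <= MAX_ISOFORMS_IN_STATS]
    sutr = [i.length for c in kept for i in c if i.category == "sUTR"]
    putr = [i.length for c in kept for i in c if i.category == "pUTR"]
    dutr = [i.length for c in kept for i in c if i.category.startswith("dUTR")]
    ratios = []
    for c in kept:
        by_cat = {i.category: i.length for i in c}
        if "pUTR" in by_cat and "dUTR1" in by_cat and by_cat["pUTR"] > 0:
            ratios.append(by_cat["dUTR1"] / by_cat["pUTR"])
    bins: dict[int, int] = {}
    for c in kept:
        bins[len(c)] = bins.get(len(c), 0) + 1
    n_genes = len(kept)
    n_apa = sum(1 for c in kept if len(c) >= 2)
    return {
        "n_genes": n_genes,
        "n_isoforms": sum(len(c) for c in kept),
        "apa_fraction": n_apa / n_genes if n_genes else float("nan"),
        "median_sutr": median(sutr) if sutr else float("nan"),
        "median_putr": median(putr) if putr else float("nan"),
        "median_dutr": median(dutr) if dutr else float("nan"),
        "median_dutr1_putr_ratio": median(ratios) if ratios else float("nan"),
        "isoform_count_bins": dict(sorted(bins.items())),
    }
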