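"""Change-point detection of candidate 3' ends downstream of stop codons.

Coverage downstream of a gene's stop codon is projected into UTR coordinates
(nt after stop, mRNA orientation) and segmented under a piecewise-constant
Poisson model by recursive binary segmentation.  A split is accepted only when
it produces a sustained *drop* of coverage that passes the ``min_fold``
criterion, which distinguishes terminal-exon boundaries from local dips.

Parameter semantics:

* ``min_fold`` -- a change point is accepted when the downstream/upstream mean
  ratio is <= ``min_fold``; larger values admit shallower steps and therefore
  more isoforms.
* ``merge_radius`` -- zero-coverage runs up to this length are bridged
  (assembly gap tolerance); a longer run terminates the scan.
* ``max_isoform`` -- cap on the number of segments per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .coverage_io import CoverageTrack
from .gene_models import GeneModel

log = logging.getLogger(__name__)

VERY_SHORT_NT = 100  # UTR lengths below this are flagged as low-reliability

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the end detector (defaults = the pipeline's working values)."""

    min_fold: float = 0.8
    merge_radius: int = 200
    max_isoform: int = 20
    precision_window: int = 100
    min_segment_len: int = 100
    scan_cap: int = 20_000
    # Model-selection guard: a split must improve the Poisson log-likelihood by
    # more than split_penalty_factor * ln(vector length) to be accepted (a
    # BIC-style penalty for the extra mean + boundary), which separates
    # sustained coverage drops from the best-of-many noise fluctuation.
    split_penalty_factor: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.min_fold <= 1:
            raise ValueError("min_fold must be in (0, 1]")
        if self.split_penalty_factor < 0:
            raise ValueError("split_penalty_factor must be >= 0")
        if min(self.merge_radius, self.max_isoform, self.precision_window,
               self.min_segment_len, self.scan_cap) <= 0:
            raise ValueError("all segmentation parameters must be positive")
        if self.min_segment_len > self.scan_cap:
            raise ValueError("min_segment_len must not exceed scan_cap")


@dataclass(frozen=True)
class TerminalEnd:
    """One candidate 3' end in UTR coordinates (1 = first base after stop)."""

    gene_id: str
    utr_pos: int
    upstream_mean: float
    downstream_mean: float
    very_short: bool = False

    @property
    def drop_ratio(self) -> float:
        if self.upstream_mean == 0:
            return float("nan")
        return self.downstream_mean / self.upstream_mean


def truncate_at_gap(v: np.ndarray, merge_radius: int) -> np.ndarray:
    """Clip a UTR coverage vector at the first zero-run longer than ``merge_radius``.

    Internal zero runs up to ``merge_radius`` nt are retained; trailing zeros
    are always trimmed so the vector ends on the last covered base.
    """
    v = np.asarray(v, dtype=float)
    nz = np.flatnonzero(v > 0)
    if nz.size == 0:
        return v[:0]
    if nz[0] > merge_radius:  # gap right after the stop codon
        return v[:0]
    gaps = np.diff(nz) - 1
    over = np.flatnonzero(gaps > merge_radius)
    last = nz[over[0]] if over.size else nz[-1]
    return v[: last + 1]


def scan_region(
    track: CoverageTrack,
    gene: GeneModel,
    neighbors: Sequence[GeneModel],
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Project masked coverage downstream of the stop codon into UTR coordinates.

    The scan is bounded by the earliest of: ``scan_cap``, the mask/region
    boundary, and the nearest neighboring gene's CDS edge in mRNA direction.
    Returns the (possibly empty) vector v with v[i] = depth at utr_pos i+1.
    """
    if gene.strand == "+":
        bound = track.end
        for n in neighbors:
            if n.gene_id != gene.gene_id and n.cds_start >= gene.stop_anchor:
                bound = min(bound, n.cds_start)
        length = bound - gene.stop_anchor
    else:
        bound = track.start
        for n in neighbors:
            if n.gene_id != gene.gene_id and n.cds_end <= gene.stop_anchor:
                bound = max(bound, n.cds_end)
        length = gene.stop_anchor - bound
    length = min(length, params.scan_cap)
    if length <= 0:
        log.info("gene %s: stop codon at region edge, unannotatable", gene.gene_id)
        return np.zeros(0)
    if gene.strand == "+":
        v = track.slice(gene.stop_anchor, gene.stop_anchor + length)
    else:
        v = track.slice(gene.stop_anchor - length, gene.stop_anchor)[::-1]
    return truncate_at_gap(v, params.merge_radius)


def _poisson_cost(total: float, n: int) -> float:
    """Negative log-likelihood (up to data-only constants) of one constant-mean segment."""
    if total <= 0:
        return 0.0
    return total - total * np.log(total / n)


def _best_split(cum: np.ndarray, lo: int, hi: int, min_len: int) -> int | None:
    """Split position minimizing the two-segment Poisson cost; downstream-most on ties."""
    first, last = lo + min_len, hi - min_len
    if first > last:
        return None
    s = np.arange(first, last + 1)
    s1 = cum[s] - cum[lo]
    s2 = cum[hi] - cum[s]
    n1 = s - lo
    n2 = hi - s
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = np.where(s1 > 0, s1 - s1 * np.log(s1 / n1), 0.0)
        c2 = np.where(s2 > 0, s2 - s2 * np.log(s2 / n2), 0.0)
    cost = c1 + c2
    best = cost.min()
    return int(s[np.flatnonzero(cost <= best + _TIE_EPS)[-1]])


def segment_changepoints(
    v: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    gene_id: str = "",
) -> list[TerminalEnd]:
    """Detect 3' ends in a UTR coverage vector by constrained binary segmentation.

    Recursively places the split minimizing the total Poisson negative
    log-likelihood of a piecewise-constant model; a split is kept only when
    both children reach ``min_segment_len``, the downstream mean is below the
    upstream mean, their ratio is <= ``min_fold``, and the likelihood gain
    clears the model-selection penalty.  Returned ends are the
    accepted split positions plus the extinction end (last covered base),
    sorted by position.  Appending trailing zeros does not change the result.
    """
    v = np.asarray(v, dtype=float)
    nz = np.flatnonzero(v > 0)
    if nz.size == 0:
        return []
    v = v[: nz[-1] + 1]
    cum = np.concatenate(([0.0], np.cumsum(v)))
    n = len(v)

    splits: list[int] = []
    penalty = params.split_penalty_factor * np.log(n)

    def recurse(lo: int, hi: int) -> None:
        if len(splits) + 1 >= params.max_isoform:
            return
        s = _best_split(cum, lo, hi, params.min_segment_len)
        if s is None:
            return
        m1 = (cum[s] - cum[lo]) / (s - lo)
        m2 = (cum[hi] - cum[s]) / (hi - s)
        if not (m1 > 0 and m2 < m1 and m2 / m1 <= params.min_fold):
            return
        gain = (
            _poisson_cost(cum[hi] - cum[lo], hi - lo)
            - _poisson_cost(cum[s] - cum[lo], s - lo)
            - _poisson_cost(cum[hi] - cum[s], hi - s)
        )
        if gain <= penalty:
            return
        splits.append(s)
        recurse(lo, s)
        recurse(s, hi)

    recurse(0, n)
    bounds = [0] + sorted(splits) + [n]
    means = [
        (cum[b] - cum[a]) / (b - a) for a, b in zip(bounds, bounds[1:])
    ]
    ends: list[TerminalEnd] = []
    for i in range(1, len(bounds) - 1):
        ends.append(
            TerminalEnd(
                gene_id=gene_id,
                utr_pos=bounds[i],
                upstream_mean=means[i - 1],
                downstream_mean=means[i],
            )
        )
    ends.append(
        TerminalEnd(
            gene_id=gene_id,
            utr_pos=n,
            upstream_mean=means[-1],
            downstream_mean=0.0,
        )
    )
    return ends


def filter_ends(ends: Sequence[TerminalEnd], gene: GeneModel | None = None) -> list[TerminalEnd]:
    """Drop ends upstream of the stop codon and flag very short UTRs (< 100 nt)."""
    out: list[TerminalEnd] = []
    for e in ends:
        if e.utr_pos < 1:  # cannot occur by construction; guard retained
            continue
        out.append(replace(e, very_short=e.utr_pos < VERY_SHORT_NT))
    return out
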