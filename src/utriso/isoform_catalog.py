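"""From raw terminal ends to polyA sites and ranked 3'UTR isoforms.

Ends closer than the 100-nt precision window are indistinguishable at the
resolution of the assembly and are merged into one polyA site by single
linkage.  Isoform spans that run into a neighboring gene are discarded as
presumed fusion artifacts.  Surviving sites become ranked isoforms:
``sUTR`` (single), ``pUTR`` (proximal of several) and ``dUTR1..n`` (distal,
numbered by increasing length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .end_detection import VERY_SHORT_NT
from .gene_models import GeneModel

PRECISION_WINDOW = 100  # nt; ends closer than this merge into one site
MAX_ISOFORMS_IN_STATS = 5  # genes with more isoforms are excluded from summaries


@dataclass(frozen=True)
class PolyASite:
    """A merged cluster of RNA-Seq-deduced 3' ends (UTR coordinates)."""

    gene_id: str
    member_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.member_ends:
            raise ValueError("PolyASite needs at least one member end")
        if list(self.member_ends) != sorted(self.member_ends):
            raise ValueError("member_ends must be sorted")

    @property
    def representative_end(self) -> int:
        """Distal-most member; the single length used downstream."""
        return self.member_ends[-1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.member_ends[0], self.member_ends[-1])

    @property
    def very_short(self) -> bool:
        return self.representative_end < VERY_SHORT_NT


@dataclass(frozen=True)
class UtrIsoform:
    """One ranked 3'UTR isoform of a gene."""

    gene_id: str
    rank: int  # 1..n by length ascending
    length: int  # nt after stop (representative end)
    category: str  # sUTR / pUTR / dUTR1..
    very_short: bool
    in_stats: bool
    relative_abundance: float | None = None


def merge_ends(
    ends: Sequence[int], window: int = PRECISION_WINDOW, gene_id: str = ""
) -> list[PolyASite]:
    """Single-linkage merge of 3' ends distant by less than ``window`` nt.

    Adjacent ends with a strict gap < window chain into one site; the merge is
    transitive, so a chained cluster may span >= window overall.  Merging the
    representatives of its own output changes nothing (idempotence).
    """
    ordered = sorted(ends)
    if not ordered:
        return []
    clusters: list[list[int]] = [[ordered[0]]]
    for e in ordered[1:]:
        if e - clusters[-1][-1] < window:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    return [PolyASite(gene_id=gene_id, member_ends=tuple(c)) for c in clusters]


def discard_fusions(
    spans: Sequence[tuple[str, int, int]],
    genes: Sequence[GeneModel] | Mapping[str, GeneModel],
    stranded: bool = True,
) -> tuple[list[tuple[str, int, int]], list[dict]]:
    """Discard isoform spans that run into another gene (presumed fusions).

    ``spans`` are genomic half-open intervals (stop codon to representative
    end) keyed by gene_id.  A span is discarded when it overlaps another
    *target* gene's CDS on either strand, or a non-target gene's CDS on the
    same strand (any strand when the data are unstranded, where coverage of
    the two strands superposes).  Returns (kept, discard log).
    """
    if isinstance(genes, Mapping):
        gene_map = dict(genes)
    else:
        gene_map = {g.gene_id: g for g in genes}
    all_genes = list(gene_map.values())

    kept: list[tuple[str, int, int]] = []
    discarded: list[dict] = []
    for gid, start, end in spans:
        g = gene_map[gid]
        offender = None
        for other in all_genes:
            if other.gene_id == gid or other.chrom != g.chrom:
                continue
            if not (start < other.cds_end and other.cds_start < end):
                continue
            if other.is_target or not stranded or other.strand == g.strand:
                offender = other
                break
        if offender is None:
            kept.append((gid, start, end))
        else:
            discarded.append(
                {"gene_id": gid, "span": (start, end), "overlaps": offender.gene_id}
            )
    return kept, discarded


def catalog(gene: GeneModel | str, sites: Sequence[PolyASite]) -> list[UtrIsoform]:
    """Rank merged polyA sites into categorized isoforms.

    Category is a pure function of (rank, n): the only isoform is ``sUTR``;
    with APA, rank 1 is ``pUTR`` and rank k+1 is ``dUTRk`` (numbered by
    increasing length).  Genes with more than 5 isoforms are catalogued but
    flagged out of the summary statistics.  An empty site list is a valid
    outcome (gene unannotated).
    """
    gene_id = gene if isinstance(gene, str) else gene.gene_id
    ordered = sorted(sites, key=lambda s: s.representative_end)
    lengths = [s.representative_end for s in ordered]
    if len(set(lengths)) != len(lengths):
        raise ValueError(f"{gene_id}: duplicate isoform lengths after merging")
    n = len(ordered)
    in_stats = n <= MAX_ISOFORMS_IN_STATS
    out: list[UtrIsoform] = []
    for rank, site in enumerate(ordered, start=1):
        if n == 1:
            category = "sUTR"
        elif rank == 1:
            category = "pUTR"
        else:
            category = f"dUTR{rank - 1}"
        out.append(
            UtrIsoform(
                gene_id=gene_id,
                rank=rank,
                length=site.representative_end,
                category=category,
                very_short=site.very_short,
                in_stats=in_stats,
            )
        )
    return out
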