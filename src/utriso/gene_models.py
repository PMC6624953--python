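"""Gene annotation parsing, stop-codon anchors and target-family mask regions.

Genes of the target family (e.g. mouse odorant-receptor ``Olfr`` genes) sit in
dense genomic clusters.  This module reduces a GENCODE-style GTF to one compact
record per gene -- the CDS envelope across all isoforms plus a strand-aware
stop-codon anchor -- and builds the genomic mask regions that restrict all
downstream coverage analysis to the clusters of interest.

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
BED (0-based half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gffutils

log = logging.getLogger(__name__)

EDGE_DEFAULT = 25_000  # nt added beyond a terminal target CDS with no flanking gene

# Gap between transcript clusters above which a `set_alt_locus` override splits
# a gene into independent loci.
ALT_LOCUS_GAP = 100_000


class AnnotationError(ValueError):
    """Raised for irreconcilable gene annotations (e.g. multiple stop anchors)."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: CDS envelope, strand and the 3'-most stop-codon boundary.

    ``stop_anchor`` is the genomic coordinate of the mRNA-orientation 3'
    boundary of the stop codon: for ``+`` genes the 0-based *exclusive* end of
    the CDS region (first UTR base is ``stop_anchor`` itself), for ``-`` genes
    the 0-based *inclusive* start (first UTR base is ``stop_anchor - 1``).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    stop_anchor: int
    is_target: bool
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.cds_end <= self.cds_start:
            raise ValueError(f"empty cds_span for {self.gene_id}")

    @property
    def cds_span(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    def utr_to_genomic(self, utr_pos: int) -> int:
        """Genomic 0-based coordinate of the base at ``utr_pos`` (1 = first base after stop)."""
        if self.strand == "+":
            return self.stop_anchor + utr_pos - 1
        return self.stop_anchor - utr_pos

    def utr_span_genomic(self, length: int) -> tuple[int, int]:
        """Genomic half-open span of a 3'UTR of ``length`` nt after the stop codon."""
        if self.strand == "+":
            return (self.stop_anchor, self.stop_anchor + length)
        return (self.stop_anchor - length, self.stop_anchor)


@dataclass(frozen=True)
class MaskRegion:
    """A run of consecutive target-gene CDSs bounded by the flanking non-target CDSs."""

    region_id: int
    chrom: str
    start: int
    end: int
    member_gene_ids: tuple[str, ...]
    gene_density: float  # member CDS count per Mb of flanking-to-flanking distance

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CurationOverride:
    """One manual-curation rule applied while parsing gene models.

    actions:
      drop_transcript  payload = transcript_id to ignore
      drop_gene        payload ignored
      force_region_span payload = "chrom:start-end" (0-based half-open)
      set_alt_locus    payload ignored; transcript clusters separated by more
                       than ``ALT_LOCUS_GAP`` become independent loci named
                       ``<gene_id>@1``, ``<gene_id>@2`` ...
    """

    gene_id: str
    action: str
    payload: str = ""

    VALID_ACTIONS = ("drop_transcript", "drop_gene", "force_region_span", "set_alt_locus")

    def __post_init__(self) -> None:
        if self.action not in self.VALID_ACTIONS:
            raise ValueError(f"unknown curation action {self.action!r}")


def read_curation(path: str | Path) -> list[CurationOverride]:
    """Read tab-separated curation overrides: gene_id <TAB> action [<TAB> payload]."""
    out: list[CurationOverride] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"curation file line {i}: expected gene_id<TAB>action")
        out.append(CurationOverride(parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    return out


def _as_predicate(target_predicate: str | Callable[[str], bool]) -> Callable[[str], bool]:
    if callable(target_predicate):
        return target_predicate
    pattern = re.compile(target_predicate)
    return lambda name: bool(pattern.match(name))


def _cluster_loci(spans: dict[str, tuple[int, int]], gap: int = ALT_LOCUS_GAP) -> list[list[str]]:
    """Group transcript spans into loci separated by more than ``gap`` nt."""
    ordered = sorted(spans, key=lambda t: spans[t][0])
    clusters: list[list[str]] = [[ordered[0]]]
    cur_end = spans[ordered[0]][1]
    for tid in ordered[1:]:
        s, e = spans[tid]
        if s - cur_end > gap:
            clusters.append([tid])
        else:
            clusters[-1].append(tid)
        cur_end = max(cur_end, e)
    return clusters


def parse_gene_models(
    gtf_path: str | Path,
    target_predicate: str | Callable[[str], bool],
    curation: Sequence[CurationOverride] | str | Path | None = None,
) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF into :class:`GeneModel` records.

    The CDS envelope of a gene is the union over all of its isoforms' CDS and
    stop-codon features (the maximal start-to-stop extent).  The stop anchor is
    taken from stop_codon features, or inferred from the CDS 3' boundary for
    transcripts lacking one.  Genes without any CDS (pseudogenes) are skipped
    with a log message.  Genes whose transcripts disagree on the stop anchor
    must be resolved through the curation file, otherwise an
    :class:`AnnotationError` listing them is raised.
    """
    predicate = _as_predicate(target_predicate)
    if curation is None:
        overrides: list[CurationOverride] = []
    elif isinstance(curation, (str, Path)):
        overrides = read_curation(curation)
    else:
        overrides = list(curation)

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # gene_id -> transcript_id -> list of (kind, start0, end0)
    per_gene: dict[str, dict[str, list[tuple[str, int, int]]]] = {}
    meta: dict[str, dict[str, str]] = {}
    for kind in ("CDS", "stop_codon"):
        for feat in db.features_of_type(kind):
            gid = feat.attributes.get("gene_id", ["?"])[0]
            tid = feat.attributes.get("transcript_id", [gid])[0]
            gname = feat.attributes.get("gene_name", [gid])[0]
            meta.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand, "name": gname})
            per_gene.setdefault(gid, {}).setdefault(tid, []).append(
                (kind, feat.start - 1, feat.end)
            )

    by_gene: dict[str, list[CurationOverride]] = {}
    for ov in overrides:
        by_gene.setdefault(ov.gene_id, []).append(ov)

    used_overrides: set[int] = set()
    models: list[GeneModel] = []
    multi_stop: list[str] = []

    for gid in sorted(per_gene):
        transcripts = per_gene[gid]
        ovs = by_gene.get(gid, [])
        for ov in ovs:
            used_overrides.add(id(ov))
        if any(ov.action == "drop_gene" for ov in ovs):
            log.info("gene %s dropped by curation", gid)
            continue
        dropped = {ov.payload for ov in ovs if ov.action == "drop_transcript"}
        transcripts = {tid: fs for tid, fs in transcripts.items() if tid not in dropped}
        if not transcripts:
            log.info("gene %s: all transcripts dropped by curation; skipped", gid)
            continue

        # Split multi-locus genes when requested.
        if any(ov.action == "set_alt_locus" for ov in ovs):
            spans = {
                tid: (min(s for _, s, _ in fs), max(e for _, _, e in fs))
                for tid, fs in transcripts.items()
            }
            clusters = _cluster_loci(spans)
        else:
            clusters = [list(transcripts)]

        for locus_idx, tids in enumerate(clusters, start=1):
            locus_id = gid if len(clusters) == 1 else f"{gid}@{locus_idx}"
            feats = [f for tid in tids for f in transcripts[tid]]
            info = meta[gid]
            strand = info["strand"]
            cds_start = min(s for _, s, _ in feats)
            cds_end = max(e for _, _, e in feats)

            anchors: set[int] = set()
            for tid in tids:
                fs = transcripts[tid]
                stops = [(s, e) for kind, s, e in fs if kind == "stop_codon"]
                cdss = [(s, e) for kind, s, e in fs if kind == "CDS"]
                source = stops if stops else cdss
                if not source:
                    continue
                if strand == "+":
                    anchors.add(max(e for _, e in source))
                else:
                    anchors.add(min(s for s, _ in source))
            if not anchors:
                log.info("gene %s: no stop codon and no CDS to infer from; skipped", locus_id)
                continue
            if len(anchors) > 1:
                multi_stop.append(locus_id)
                continue
            models.append(
                GeneModel(
                    gene_id=locus_id,
                    chrom=info["chrom"],
                    strand=strand,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    stop_anchor=anchors.pop(),
                    is_target=predicate(info["name"]),
                    gene_name=info["name"],
                )
            )

    for ov in overrides:
        if id(ov) not in used_overrides:
            log.warning("curation override for unknown gene %s unused", ov.gene_id)

    if multi_stop:
        raise AnnotationError(
            "multiple irreconcilable stop anchors (resolve via curation file): "
            + ", ".join(sorted(multi_stop))
        )
    models.sort(key=lambda g: (g.chrom, g.cds_start, g.gene_id))
    return models


def build_mask(
    genes: Sequence[GeneModel],
    edge_default: int = EDGE_DEFAULT,
    overrides: Sequence[CurationOverride] | None = None,
) -> list[MaskRegion]:
    """Group consecutive target CDSs into mask regions.

    A region spans from the proximal (cluster-facing) end of the closest
    upstream non-target CDS to the proximal end of the closest downstream
    non-target CDS.  Where a chromosome has no flanking non-target gene the
    boundary is placed ``edge_default`` nt beyond the terminal target CDS.
    Gene density is the member CDS count per Mb of the region span.
    """
    forced: dict[str, tuple[str, int, int]] = {}
    for ov in overrides or []:
        if ov.action == "force_region_span":
            chrom, span = ov.payload.split(":")
            s, e = span.split("-")
            forced[ov.gene_id] = (chrom, int(s), int(e))

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    regions: list[MaskRegion] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.cds_start, g.gene_id))
        clusters: list[list[GeneModel]] = []
        upstream_nt: list[GeneModel | None] = []  # flanking non-target per cluster
        downstream_nt: list[GeneModel | None] = []
        last_nontarget: GeneModel | None = None
        current: list[GeneModel] | None = None
        for g in ordered:
            if g.is_target:
                if current is None:
                    current = []
                    clusters.append(current)
                    upstream_nt.append(last_nontarget)
                    downstream_nt.append(None)
                current.append(g)
            else:
                if current is not None:
                    downstream_nt[len(clusters) - 1] = g
                    current = None
                last_nontarget = g

        for members, up, down in zip(clusters, upstream_nt, downstream_nt):
            forced_span = next(
                (forced[g.gene_id] for g in members if g.gene_id in forced), None
            )
            if forced_span is not None:
                _, start, end = forced_span
            else:
                start = up.cds_end if up is not None else max(
                    0, members[0].cds_start - edge_default
                )
                end = down.cds_start if down is not None else members[-1].cds_end + edge_default
            if end <= start:
                raise AnnotationError(
                    f"non-positive mask span on {chrom} for genes "
                    + ", ".join(g.gene_id for g in members)
                )
            density = len(members) / ((end - start) / 1e6)
            regions.append(
                MaskRegion(
                    region_id=0,  # renumbered below
                    chrom=chrom,
                    start=start,
                    end=end,
                    member_gene_ids=tuple(g.gene_id for g in members),
                    gene_density=density,
                )
            )

    regions.sort(key=lambda r: (r.chrom, r.start))
    regions = [
        MaskRegion(i + 1, r.chrom, r.start, r.end, r.member_gene_ids, r.gene_density)
        for i, r in enumerate(regions)
    ]
    # contract: regions on a chromosome must not overlap
    for a, b in zip(regions, regions[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise AnnotationError(
                f"overlapping mask regions on {a.chrom}: "
                f"{a.member_gene_ids} vs {b.member_gene_ids}"
            )
    return regions


def mask_intervals(regions: Iterable[MaskRegion]) -> list[str]:
    """Render regions as sorted BED lines (0-based half-open)."""
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\tregion_{r.region_id}"
        for r in sorted(regions, key=lambda r: (r.chrom, r.start))
    ]
    if not lines:
        return ["# empty mask: no target regions"]
    return lines


def write_mask_bed(regions: Iterable[MaskRegion], path: str | Path) -> None:
    Path(path).write_text("\n".join(mask_intervals(regions)) + "\n")


def read_mask_bed(path: str | Path) -> list[MaskRegion]:
    """Re-parse a mask BED file written by :func:`write_mask_bed`."""
    regions: list[MaskRegion] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        regions.append(
            MaskRegion(
                region_id=len(regions) + 1,
                chrom=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                member_gene_ids=(),
                gene_density=float("nan"),
            )
        )
    return regions
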