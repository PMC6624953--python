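"""Splice-junction evidence for introns inside annotated 3'UTRs.

Junctions (from an external extractor run on the alignments) are filtered to
depth > 1, deduplicated, assigned to the 3'UTR that strictly contains them,
and classified by intron-retention coverage: when the intron interior is
essentially uncovered the excision is *obligatory*; when both spliced and
unspliced reads coexist it is *optional*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .coverage_io import CoverageTrack

MIN_JUNCTION_DEPTH = 1  # junctions must have depth strictly greater than this
RETENTION_THRESHOLD = 1.0  # mean intron depth <= this => obligatory excision


@dataclass(frozen=True)
class Junction:
    """One splice junction; [donor, acceptor) is the intron, 0-based half-open."""

    chrom: str
    donor: int
    acceptor: int
    depth: float
    strand: str = "."
    name: str = ""
    contained_in: tuple[str, int] | None = None  # (gene_id, isoform rank)
    mode: str = "none"  # obligatory | optional | none

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("junction depth must be >= 0")
        if self.acceptor <= self.donor:
            raise ValueError("acceptor must lie downstream of donor")


def read_junctions(path: str | Path) -> list[Junction]:
    """Read junctions from 12-column BED (block-anchored) or 6-column TSV.

    BED12 rows follow the junction-extract convention: the record spans the
    anchors and the two block sizes encode them, so the intron is
    [start + size1, end - size2).  The 6-column form is
    chrom, donor, acceptor, name, depth, strand.
    """
    out: list[Junction] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        try:
            if len(parts) >= 12:
                start, end = int(parts[1]), int(parts[2])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                out.append(
                    Junction(
                        chrom=parts[0],
                        donor=start + sizes[0],
                        acceptor=end - sizes[1],
                        depth=float(parts[4]),
                        strand=parts[5],
                        name=parts[3],
                    )
                )
            elif len(parts) >= 6:
                out.append(
                    Junction(
                        chrom=parts[0],
                        donor=int(parts[1]),
                        acceptor=int(parts[2]),
                        depth=float(parts[4]),
                        strand=parts[5],
                        name=parts[3],
                    )
                )
            else:
                raise ValueError("expected 6 or 12 columns")
        except (ValueError, IndexError) as err:
            raise ValueError(f"{path}: malformed junction line {lineno}: {err}") from None
    return out


def filter_junctions(junctions: Sequence[Junction]) -> list[Junction]:
    """Keep junctions with depth > 1 and the best-scoring duplicate per intron."""
    best: dict[tuple[str, int, int, str], Junction] = {}
    for j in junctions:
        if j.depth <= MIN_JUNCTION_DEPTH:
            continue
        key = (j.chrom, j.donor, j.acceptor, j.strand)
        if key not in best or j.depth > best[key].depth:
            best[key] = j
    return sorted(best.values(), key=lambda j: (j.chrom, j.donor, j.acceptor))


def classify_intron(
    junction: Junction,
    utr_span: tuple[int, int],
    coverage: CoverageTrack,
    retention_threshold: float = RETENTION_THRESHOLD,
) -> str:
    """Obligatory/optional call for a junction against one 3'UTR span.

    The junction must be strictly inside the genomic UTR span, otherwise
    ``"none"``.  Mean coverage of the intron interior at or below
    ``retention_threshold`` means the intron is always excised (obligatory);
    higher retention coverage means the unspliced form coexists (optional).
    """
    us, ue = utr_span
    if not (us < junction.donor and junction.acceptor < ue):
        return "none"
    mean_depth = coverage.window_sum(junction.donor, junction.acceptor) / (
        junction.acceptor - junction.donor
    )
    return "obligatory" if mean_depth <= retention_threshold else "optional"


def annotate_introns(
    junctions: Sequence[Junction],
    utr_spans: Sequence[tuple[str, int, str, int, int]],
    tracks: Sequence[CoverageTrack],
    retention_threshold: float = RETENTION_THRESHOLD,
) -> list[Junction]:
    """Assign filtered junctions to containing 3'UTRs and classify them.

    ``utr_spans`` rows are (gene_id, isoform rank, chrom, genomic start, end).
    A junction is annotated against the first (most proximal-rank) isoform
    span that strictly contains it on the same chromosome.
    """
    track_by_chrom: dict[str, list[CoverageTrack]] = {}
    for t in tracks:
        track_by_chrom.setdefault(t.chrom, []).append(t)
    out: list[Junction] = []
    for j in filter_junctions(junctions):
        annotated = j
        for gene_id, rank, chrom, us, ue in sorted(utr_spans, key=lambda r: r[1]):
            if chrom != j.chrom or not (us < j.donor and j.acceptor < ue):
                continue
            track = next(
                (t for t in track_by_chrom.get(chrom, []) if t.start <= us and ue <= t.end),
                None,
            )
            if track is None:
                continue
            mode = classify_intron(j, (us, ue), track, retention_threshold)
            if mode != "none":
                annotated = replace(j, contained_in=(gene_id, rank), mode=mode)
                break
        out.append(annotated)
    return out
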