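"""PolyA-signal (PAS) hexamer scanning around called 3' ends.

Cleavage/polyadenylation is directed by a hexamer signal upstream of the
cleavage site -- canonically AAUAAA or AUUAAA in the mRNA.  Sequences are
handled in the DNA alphabet (AATAAA/ATTAAA) in mRNA-sense orientation, with
position 1 being the first base after the stop codon.  A canonical signal
validates a called end when it starts within [-100, +100] nt of any member of
the merged site (both bounds inclusive); variant hexamers are only searched
upstream ([-100, 0]) and only for sites lacking a canonical match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .gene_models import GeneModel
from .isoform_catalog import PolyASite

CANONICAL_HEXAMERS = ("AATAAA", "ATTAAA")

# Default variant list: the most common non-canonical single-base variants and
# related weak signals described for mouse/human polyA sites.  Editable --
# pass any 16-mer... any set of hexamers to the scanning functions or a file
# of one hexamer per line on the CLI.
DEFAULT_VARIANT_HEXAMERS = (
    "TATAAA", "AGTAAA", "AAGAAA", "AATATA", "AATACA", "CATAAA",
    "GATAAA", "AATGAA", "TTTAAA", "ACTAAA", "AATAGA", "AATAAT",
    "AACAAA", "ATTACA", "ATTATA", "AACAAG",
)

CANONICAL_WINDOW = (-100, 100)
VARIANT_WINDOW = (-100, 0)

_ALPHABET = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def load_hexamer_file(path: str | Path) -> tuple[str, ...]:
    """Read one hexamer per line (RNA U accepted, converted to DNA T)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip().upper().replace("U", "T")
        if not line or line.startswith("#"):
            continue
        if len(line) != 6 or not set(line) <= set("ACGT"):
            raise ValueError(f"invalid hexamer {line!r} in {path}")
        out.append(line)
    return tuple(out)


@dataclass(frozen=True)
class PASMatch:
    """A hexamer matched to a called 3' end."""

    gene_id: str
    hexamer: str
    pas_pos: int  # utr_pos of hexamer start
    end_pos: int  # utr_pos of the matched 3' end
    kind: str  # canonical | variant

    @property
    def offset(self) -> int:
        return self.pas_pos - self.end_pos


def utr_sequence(genome: str | dict[str, str], gene: GeneModel, length: int) -> str:
    """mRNA-sense sequence of the first ``length`` nt after the stop codon."""
    seq = genome if isinstance(genome, str) else genome[gene.chrom]
    start, end = gene.utr_span_genomic(length)
    sub = seq[max(start, 0) : end].upper()
    if gene.strand == "-":
        sub = reverse_complement(sub)
    return sub


def scan_hexamers(seq: str, hexamers: Iterable[str]) -> list[tuple[str, int]]:
    """All exact (overlapping) hexamer matches as (hexamer, 1-based utr_pos of start)."""
    seq = seq.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    hits: list[tuple[str, int]] = []
    for hexamer in hexamers:
        start = seq.find(hexamer)
        while start != -1:
            hits.append((hexamer, start + 1))
            start = seq.find(hexamer, start + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def match_pas(
    site: PolyASite,
    hits: Sequence[tuple[str, int]],
    window: tuple[int, int] = CANONICAL_WINDOW,
) -> list[PASMatch]:
    """Match hexamer hits to a merged polyA site.

    A hexamer matches when its offset to *any* member end of the site falls in
    ``window`` (inclusive); one match per hexamer position, attributed to the
    member end with the smallest absolute offset.
    """
    lo, hi = window
    out: list[PASMatch] = []
    for hexamer, pos in hits:
        in_window = [e for e in site.member_ends if lo <= pos - e <= hi]
        if not in_window:
            continue
        end = min(in_window, key=lambda e: (abs(pos - e), e))
        out.append(
            PASMatch(gene_id=site.gene_id, hexamer=hexamer, pas_pos=pos,
                     end_pos=end, kind="canonical")
        )
    return out


def match_variant_pas(
    cleavage_pos: int,
    hits: Sequence[tuple[str, int]],
    window: tuple[int, int] = VARIANT_WINDOW,
    gene_id: str = "",
) -> list[PASMatch]:
    """Upstream-only variant-hexamer matching for ends lacking a canonical PAS."""
    lo, hi = window
    return [
        PASMatch(gene_id=gene_id, hexamer=hexamer, pas_pos=pos,
                 end_pos=cleavage_pos, kind="variant")
        for hexamer, pos in hits
        if lo <= pos - cleavage_pos <= hi
    ]


def canonical_fraction(matches_per_site: Sequence[Sequence[PASMatch]]) -> float:
    """Fraction of sites with at least one canonical PAS match."""
    if not matches_per_site:
        return float("nan")
    hit = sum(1 for m in matches_per_site if any(x.kind == "canonical" for x in m))
    return hit / len(matches_per_site)
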