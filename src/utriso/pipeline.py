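"""End-to-end orchestration: mask -> coverage -> detect -> catalog -> PAS -> quantify.

``run_pipeline`` processes one dataset region by region (regions are
independent; any processing order yields identical results) and writes the
per-gene tables; ``compare_runs`` aligns the catalogs of several runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .compare_datasets import DatasetLabel, common_genes, conservation_table
from .coverage_io import CoverageTrack, expression_status, load_bedgraph
from .end_detection import SegmentationParams, filter_ends, scan_region, segment_changepoints
from .gene_models import (
    GeneModel,
    MaskRegion,
    build_mask,
    parse_gene_models,
    read_curation,
    write_mask_bed,
)
from .isoform_catalog import PolyASite, catalog, discard_fusions, merge_ends
from .pas_scan import (
    CANONICAL_HEXAMERS,
    DEFAULT_VARIANT_HEXAMERS,
    match_pas,
    match_variant_pas,
    scan_hexamers,
    utr_sequence,
)
from .quantify_profile import length_stats, quantify_gene
from .utr_introns import annotate_introns, read_junctions

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one dataset run."""

    gtf: str | Path
    bedgraph: str | Path | Mapping[str, str | Path]  # single file or {strand: file}
    outdir: str | Path
    targets: str = "^Olfr"
    fasta: str | Path | None = None
    junctions: str | Path | None = None
    curation: str | Path | None = None
    variant_hexamers: Sequence[str] = DEFAULT_VARIANT_HEXAMERS
    params: SegmentationParams = field(default_factory=SegmentationParams)
    dataset_name: str = "dataset"
    seed: int = 0

    def __post_init__(self) -> None:
        paths = [self.gtf, self.fasta, self.junctions, self.curation]
        if isinstance(self.bedgraph, Mapping):
            paths.extend(self.bedgraph.values())
        else:
            paths.append(self.bedgraph)
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


def _load_tracks(
    config: RunConfig, regions: Sequence[MaskRegion]
) -> tuple[dict[str, list[CoverageTrack]], bool]:
    """Return {strand: tracks}; '.' key for unstranded data."""
    if isinstance(config.bedgraph, Mapping):
        return (
            {s: load_bedgraph(p, regions, strand=s) for s, p in config.bedgraph.items()},
            True,
        )
    return {".": load_bedgraph(config.bedgraph, regions)}, False


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on one dataset; returns the result tables (DataFrames).

    Writes mask.bed, expression.tsv, ends.tsv, catalog.tsv, pas.tsv,
    profiles.tsv, introns.tsv (when junctions given), summary.json and
    run_log.json into ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    curation = read_curation(config.curation) if config.curation else []
    genes = parse_gene_models(config.gtf, config.targets, curation)
    regions = build_mask(genes, overrides=curation)
    write_mask_bed(regions, outdir / "mask.bed")
    gene_map = {g.gene_id: g for g in genes}

    tracks_by_strand, stranded = _load_tracks(config, regions)
    genome = (
        {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(config.fasta), "fasta")}
        if config.fasta
        else None
    )

    expr_rows, end_rows = [], []
    per_gene_sites: dict[str, list[PolyASite]] = {}
    utr_vectors: dict[str, np.ndarray] = {}
    gene_track: dict[str, CoverageTrack] = {}

    for ri, region in enumerate(regions):
        members = [gene_map[gid] for gid in region.member_gene_ids]
        neighbors = [g for g in genes if g.chrom == region.chrom]
        for gene in members:
            key = gene.strand if stranded else "."
            track = tracks_by_strand.get(key, tracks_by_strand.get("."))[ri]
            status = expression_status(track, gene)
            expr_rows.append(vars(status) | {"region_id": region.region_id})
            if not status.expressed:
                continue
            v = scan_region(track, gene, neighbors, config.params)
            if v.size == 0:
                continue
            ends = filter_ends(segment_changepoints(v, config.params, gene.gene_id))
            if not ends:
                continue
            for e in ends:
                end_rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "utr_pos": e.utr_pos,
                        "genomic_pos": gene.utr_to_genomic(e.utr_pos),
                        "upstream_mean": e.upstream_mean,
                        "downstream_mean": e.downstream_mean,
                        "drop_ratio": e.drop_ratio,
                        "very_short": e.very_short,
                    }
                )
            per_gene_sites[gene.gene_id] = merge_ends(
                [e.utr_pos for e in ends],
                window=config.params.precision_window,
                gene_id=gene.gene_id,
            )
            utr_vectors[gene.gene_id] = v
            gene_track[gene.gene_id] = track

    # fusion-transcript discard on the distal-most isoform span of each gene
    spans = []
    for gid, sites in per_gene_sites.items():
        g = gene_map[gid]
        s, e = g.utr_span_genomic(sites[-1].representative_end)
        spans.append((gid, s, e))
    kept, discard_log = discard_fusions(spans, gene_map, stranded=stranded)
    kept_ids = {gid for gid, _, _ in kept}
    for entry in discard_log:
        log.info(
            "fusion discard: %s span %s overlaps %s",
            entry["gene_id"], entry["span"], entry["overlaps"],
        )
    per_gene_sites = {gid: s for gid, s in per_gene_sites.items() if gid in kept_ids}

    catalog_rows, pas_rows, profile_rows = [], [], []
    catalogs = []
    utr_spans_for_introns = []
    for gid, sites in per_gene_sites.items():
        gene = gene_map[gid]
        isoforms = catalog(gene, sites)
        profile = quantify_gene(utr_vectors[gid], sites, gene_id=gid)
        profile_rows.append(
            {
                "gene_id": gid,
                "n_isoforms": profile.n_isoforms,
                "profile": profile.profile,
                "abundance": ",".join(f"{x:.4f}" for x in profile.abundance),
                "raw_abundance": ",".join(f"{x:.4f}" for x in profile.raw_abundance),
                "any_very_short": any(i.very_short for i in isoforms),
            }
        )
        isoforms = [
            replace(i, relative_abundance=ra)
            for i, ra in zip(isoforms, profile.abundance)
        ]
        catalogs.append(isoforms)
        for iso, site in zip(isoforms, sorted(sites, key=lambda s: s.representative_end)):
            gs, ge = gene.utr_span_genomic(iso.length)
            catalog_rows.append(
                {
                    "gene_id": gid,
                    "rank": iso.rank,
                    "length": iso.length,
                    "category": iso.category,
                    "relative_abundance": iso.relative_abundance,
                    "chrom": gene.chrom,
                    "genomic_start": gs,
                    "genomic_end": ge,
                    "strand": gene.strand,
                    "site_span": f"{site.span[0]}-{site.span[1]}",
                    "very_short": iso.very_short,
                    "in_stats": iso.in_stats,
                }
            )
            utr_spans_for_introns.append((gid, iso.rank, gene.chrom, gs, ge))

        if genome is not None:
            seq = utr_sequence(
                genome, gene, sites[-1].representative_end + config.params.precision_window + 10
            )
            canonical_hits = scan_hexamers(seq, CANONICAL_HEXAMERS)
            variant_hits = scan_hexamers(seq, config.variant_hexamers)
            for site in sites:
                matches = match_pas(site, canonical_hits)
                if not matches:
                    matches = match_variant_pas(
                        site.representative_end, variant_hits, gene_id=gid
                    )
                for m in matches:
                    pas_rows.append(
                        {
                            "gene_id": gid,
                            "site_end": site.representative_end,
                            "hexamer": m.hexamer,
                            "pas_pos": m.pas_pos,
                            "end_pos": m.end_pos,
                            "offset": m.offset,
                            "kind": m.kind,
                        }
                    )

    intron_rows = []
    if config.junctions:
        all_tracks = [t for ts in tracks_by_strand.values() for t in ts]
        annotated = annotate_introns(
            read_junctions(config.junctions), utr_spans_for_introns, all_tracks
        )
        for j in annotated:
            intron_rows.append(
                {
                    "chrom": j.chrom,
                    "donor": j.donor,
                    "acceptor": j.acceptor,
                    "depth": j.depth,
                    "strand": j.strand,
                    "gene_id": j.contained_in[0] if j.contained_in else "",
                    "isoform_rank": j.contained_in[1] if j.contained_in else "",
                    "mode": j.mode,
                }
            )

    frames = {
        "expression": pd.DataFrame(expr_rows),
        "ends": pd.DataFrame(end_rows),
        "catalog": pd.DataFrame(catalog_rows),
        "pas": pd.DataFrame(pas_rows),
        "profiles": pd.DataFrame(profile_rows),
        "introns": pd.DataFrame(intron_rows),
    }
    for name, df in frames.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    summary = length_stats(catalogs)
    summary["profile_bins"] = (
        frames["profiles"]["profile"].value_counts().to_dict() if profile_rows else {}
    )
    summary["n_fusion_discards"] = len(discard_log)
    summary["isoform_count_bins"] = {
        str(k): v for k, v in summary["isoform_count_bins"].items()
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float) + "\n")

    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "dataset": config.dataset_name,
                "seed": config.seed,
                "params": vars(config.params),
                "stranded": stranded,
                "n_genes": len(genes),
                "n_regions": len(regions),
                "n_annotated": len(per_gene_sites),
            },
            indent=1,
        )
        + "\n"
    )
    frames["summary"] = summary
    frames["discarded_fusions"] = discard_log
    return frames


def compare_runs(
    catalog_paths: Mapping[str, str | Path],
    labels: Sequence[DatasetLabel] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Cross-dataset conservation of the catalogs written by :func:`run_pipeline`."""
    catalogs = {
        name: pd.read_csv(path, sep="\t") for name, path in catalog_paths.items()
    }
    table = conservation_table(catalogs, labels)
    overlap = common_genes(
        {name: set(df["gene_id"]) for name, df in catalogs.items()}
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
        (outdir / "overlap.json").write_text(
            json.dumps(
                {
                    "n_common": overlap["n_common"],
                    "union_size": overlap["union_size"],
                    "pair_counts": {f"{a}|{b}": v for (a, b), v in overlap["pair_counts"].items()},
                    "venn": {"|".join(k): v for k, v in overlap["venn"].items()},
                },
                indent=1,
            )
            + "\n"
        )
    return {"conservation": table, "overlap": overlap}
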