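from __future__ import annotations

import json
from pathlib import Path

import pytest
from hypothesis import settings

from utriso.pipeline import RunConfig, run_pipeline

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from utriso.synthetic_data import SyntheticSpec, generate

BUNDLE_SEED = 1


def gtf_text(features: list[tuple]) -> str:
    """Render (chrom, feature, start1, end1, strand, gene_id, transcript_id) rows."""
    lines = []
    for chrom, feature, start, end, strand, gid, tid in features:
        attrs = f'gene_id "{gid}"; transcript_id "{tid}"; gene_name "{gid}";'
        lines.append(f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_gtf(tmp_path):
    def _write(features, name="genes.gtf"):
        p = tmp_path / name
        p.write_text(gtf_text(features))
        return p

    return _write


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The stock synthetic bundle plus a full pipeline run over it."""
    root = tmp_path_factory.mktemp("bundle")
    files = generate(SyntheticSpec.default(), seed=BUNDLE_SEED, outdir=root / "data")
    frames = run_pipeline(
        RunConfig(
            gtf=files["gtf"],
            bedgraph=files["bedgraph"],
            fasta=files["fasta"],
            junctions=files["junctions"],
            outdir=root / "run",
            targets="^T",
            dataset_name="bundle",
            seed=BUNDLE_SEED,
        )
    )
    return {"files": files, "truth": files["truth"], "frames": frames, "root": root}
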