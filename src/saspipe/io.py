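"""File-based loaders for the pipeline's standard inputs.

Counterparts of the writers in :mod:`saspipe.simulate`: platforms are read
back from probes/full-length FASTA plus an annotation TSV, experiments from
expression/flags/design TSVs, and transcript loci from BED6.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .filters import ExpressionExperiment
from .simulate import PlatformDesign, ProbeSet, TranscriptRecord


def load_platform(
    name: str,
    probes_fasta: Path,
    fulllength_fasta: Path,
    annotation_tsv: Path,
    loci_bed: Path | None = None,
) -> PlatformDesign:
    """Rebuild a PlatformDesign from its on-disk representation.

    Probe FASTA headers are ``<probeset_id>|probe<k>``; annotation rows give
    probeset -> transcript/gene/orientation; loci (optional BED6) attach
    genomic coordinates to the full-length transcripts. Transcripts without
    BED entries get a placeholder locus spanning their own length.
    """
    ann = pd.read_csv(annotation_tsv, sep="\t", dtype=str, keep_default_na=False)
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fulllength_fasta), "fasta")}
    loci = read_loci_bed(loci_bed) if loci_bed else {}

    probes_by_ps: dict = {}
    for rec in SeqIO.parse(str(probes_fasta), "fasta"):
        pid = rec.id.rsplit("|", 1)[0]
        probes_by_ps.setdefault(pid, []).append(str(rec.seq).upper())

    platform = PlatformDesign(name)
    for _, row in ann.iterrows():
        pid = row["probeset_id"]
        if pid not in probes_by_ps:
            raise ValueError(f"annotation lists probeset {pid} with no probes in FASTA")
        platform.probesets[pid] = ProbeSet(
            pid,
            name,
            probes_by_ps[pid],
            row["transcript_id"],
            row["gene_id"] or None,
            row["orientation"],
        )
        tid = row["transcript_id"]
        if tid in sequences and tid not in platform.transcripts:
            chrom, start, end, strand = loci.get(tid, ("unplaced", 0, len(sequences[tid]), "+"))
            platform.transcripts[tid] = TranscriptRecord(
                tid, row["gene_id"] or None, row["orientation"], sequences[tid],
                chrom, start, end, strand,
            )
    return platform


def read_loci_bed(path: Path) -> dict:
    """BED6 -> {name: (chrom, start, end, strand)}."""
    loci = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, tid, _score, strand = line.rstrip("\n").split("\t")[:6]
            loci[tid] = (chrom, int(start), int(end), strand)
    return loci


def load_experiment(expression_tsv: Path, flags_tsv: Path, design_tsv: Path) -> ExpressionExperiment:
    expr = pd.read_csv(expression_tsv, sep="\t", index_col=0)
    flags = pd.read_csv(flags_tsv, sep="\t", index_col=0, dtype=str)
    design = pd.read_csv(design_tsv, sep="\t", index_col=0)
    return ExpressionExperiment(expr, flags, design)
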