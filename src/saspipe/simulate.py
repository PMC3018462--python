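"""Synthetic transcriptome, platform designs and expression data with planted truth.

This module builds the toy study on which the whole pipeline is exercised:

* a transcriptome in which a configurable fraction of genes carry a
  natural-antisense transcript (NAT) on the opposite strand of the same
  locus, with head-to-head, tail-to-tail or fully-overlapping geometry;
* two partially overlapping array designs — a generic sense-only platform
  with per-gene probeset redundancy, and a disease-specific platform (DSA)
  carrying sense, antisense and a small unannotated stratum — whose probes
  are verbatim 25-mer substrings of their source transcripts;
* replicated in-vitro and clinical expression matrices with planted log2
  fold changes, Gaussian replicate noise, and Present/Marginal/Absent flag
  calls obtained by thresholding the linear intensities (optionally
  corrupted at a configurable rate);
* a machine-readable :class:`GroundTruth` so downstream stages can be tested
  for exact recovery.

Transcript sequences are drawn independently per transcript (uniform ACGT).
In particular an antisense transcript's sequence is NOT the reverse
complement of its sense partner over the overlap: pairing information lives
in the annotation (shared gene id), exactly as it does in a platform's
annotation files, and exact probe matching therefore cannot bridge a
sense:antisense pair by sequence. This keeps the common/unique ground truth
structural and exactly recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import stage_rng
from .config import OVERLAP_CATEGORIES, SyntheticConfig
from .filters import ExpressionExperiment

INVITRO_CONDITIONS = (
    "parental_untreated",
    "parental_treated",
    "resistant_untreated",
    "resistant_treated",
)
#: comparison name -> (control condition, treated condition)
COMPARISONS = {
    "sensitive": ("parental_untreated", "parental_treated"),
    "resistant": ("resistant_untreated", "resistant_treated"),
}
RESPONSE_GROUPS = ("CR", "PR", "SD", "PD")

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class TranscriptRecord:
    """One transcript: id, gene, orientation, sequence and genomic locus.

    Coordinates are 0-based half-open on a toy chromosome; the 5' end of a
    plus-strand transcript is ``start``, of a minus-strand transcript the
    base at ``end - 1``.
    """

    transcript_id: str
    gene_id: str | None
    orientation: str  # sense | antisense | unassigned
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def locus(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class ProbeSet:
    """A group of short probes jointly interrogating one transcript."""

    probeset_id: str
    platform: str
    probes: list
    transcript_id: str
    gene_id: str | None
    orientation: str

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("probeset must contain at least one probe")
        for p in self.probes:
            if not p or set(p) - set("ACGT"):
                raise ValueError("probes must be nonempty ACGT strings")


@dataclass
class PlatformDesign:
    """A named platform: probesets plus the full-length transcript records."""

    name: str
    probesets: dict = field(default_factory=dict)
    transcripts: dict = field(default_factory=dict)

    @property
    def sequences(self) -> dict:
        return {tid: t.sequence for tid, t in self.transcripts.items()}

    def probesets_by_transcript(self) -> dict:
        out: dict = {}
        for ps in self.probesets.values():
            out.setdefault(ps.transcript_id, set()).add(ps.probeset_id)
        return out

    def annotation_frame(self) -> pd.DataFrame:
        rows = [
            {
                "probeset_id": ps.probeset_id,
                "transcript_id": ps.transcript_id,
                "gene_id": ps.gene_id if ps.gene_id is not None else "",
                "orientation": ps.orientation,
            }
            for ps in sorted(self.probesets.values(), key=lambda p: p.probeset_id)
        ]
        return pd.DataFrame(rows, columns=["probeset_id", "transcript_id", "gene_id", "orientation"])


@dataclass
class GroundTruth:
    """Planted structure of a synthetic run, for recovery tests.

    ``planted_effects`` maps comparison name ("sensitive", "resistant",
    "clinical") to {transcript_id: signed log2 effect}; ``planted_de`` gives
    the corresponding id sets. ``common_probesets`` and
    ``planted_sas_genes`` are filled by :func:`design_platforms`.
    """

    common_probesets: set = field(default_factory=set)
    planted_effects: dict = field(default_factory=dict)
    planted_clinical_group: dict = field(default_factory=dict)
    planted_sas_genes: set = field(default_factory=set)
    category_by_gene: dict = field(default_factory=dict)
    nat_genes: set = field(default_factory=set)

    @property
    def planted_de(self) -> dict:
        return {cmp: set(eff) for cmp, eff in self.planted_effects.items()}

    def to_json(self) -> str:
        payload = {
            "common_probesets": sorted(self.common_probesets),
            "planted_effects": {k: dict(sorted(v.items())) for k, v in sorted(self.planted_effects.items())},
            "planted_clinical_group": dict(sorted(self.planted_clinical_group.items())),
            "planted_sas_genes": sorted(self.planted_sas_genes),
            "category_by_gene": dict(sorted(self.category_by_gene.items())),
            "nat_genes": sorted(self.nat_genes),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_ALPHABET, size=length).tobytes().decode()


def _place_antisense(
    rng: np.random.Generator,
    category: str,
    s: int,
    e: int,
    strand: str,
    length_range: tuple,
) -> tuple:
    """Antisense interval for a sense transcript [s, e) on `strand`.

    Geometry is defined through 5'/3' ends: the overlap interval contains
    both 5' ends for head-to-head, both 3' ends for tail-to-tail, and one
    transcript's full extent when fully overlapping.
    """
    lo, hi = length_range
    L_s = e - s
    if category == "fully_overlapping":
        L_a = int(rng.integers(lo, min(hi, L_s) + 1))
        u = int(rng.integers(0, L_s - L_a + 1))
        return s + u, s + u + L_a
    L_a = int(rng.integers(lo, hi + 1))
    # overlap depth: at least 1 nt, strictly less than either length so that
    # neither interval contains the other
    d = int(rng.integers(1, min(L_s, L_a)))
    left_side = (category == "head_to_head") == (strand == "+")
    if left_side:
        return s - (L_a - d), s + d
    return e - d, e - d + L_a


def generate_transcriptome(config: SyntheticConfig) -> tuple:
    """Generate transcripts and the planted ground truth.

    Every gene yields one sense transcript; ``nat_fraction`` of genes
    additionally yield an opposite-strand antisense partner whose overlap
    geometry follows ``overlap_category_weights``. Planted differential
    effects for the sensitive, resistant and clinical comparisons are
    assigned here (sign drawn at random, magnitude ``effect_log2``).

    Returns (list of :class:`TranscriptRecord`, :class:`GroundTruth`).
    """
    rng = stage_rng(config.seed, 0)
    lo, hi = config.transcript_length_range
    cats = list(OVERLAP_CATEGORIES)
    weights = [config.overlap_category_weights[c] for c in cats]

    records: list = []
    truth = GroundTruth()
    margin = hi + 10
    cursor = 1000
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        gid = f"G{i + 1:0{width}d}"
        tid = f"T{i + 1:0{width}d}"
        L_s = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        s = cursor + margin
        e = s + L_s
        records.append(
            TranscriptRecord(tid, gid, "sense", _random_seq(rng, L_s), "chr1", s, e, strand)
        )
        max_end = e
        if rng.random() < config.nat_fraction:
            category = cats[int(rng.choice(len(cats), p=weights))]
            a_s, a_e = _place_antisense(rng, category, s, e, strand, (lo, hi))
            a_strand = "-" if strand == "+" else "+"
            records.append(
                TranscriptRecord(
                    tid + "as", gid, "antisense", _random_seq(rng, a_e - a_s),
                    "chr1", a_s, a_e, a_strand,
                )
            )
            truth.nat_genes.add(gid)
            truth.category_by_gene[gid] = category
            max_end = max(max_end, a_e)
        cursor = max_end + margin

    tids = [r.transcript_id for r in records]
    for cmp_name in ("sensitive", "resistant", "clinical"):
        n_de = int(round(config.de_fraction * len(tids)))
        chosen = rng.choice(len(tids), size=n_de, replace=False) if n_de else []
        effects = {}
        for j in chosen:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[tids[int(j)]] = sign * config.effect_log2
        truth.planted_effects[cmp_name] = effects
    for tid in truth.planted_effects["clinical"]:
        truth.planted_clinical_group[tid] = RESPONSE_GROUPS[int(rng.integers(0, 4))]
    return records, truth


def _draw_probes(rng: np.random.Generator, seq: str, config: SyntheticConfig) -> list:
    n_pos = len(seq) - config.probe_length + 1
    k = config.probes_per_probeset
    replace = n_pos < k
    starts = np.sort(rng.choice(n_pos, size=k, replace=replace))
    return [seq[p : p + config.probe_length] for p in starts]


def design_platforms(transcripts, config: SyntheticConfig, truth: GroundTruth) -> tuple:
    """Build the generic and disease-specific platform designs.

    ``shared_content_fraction`` of genes appear on both platforms; the
    remainder is split evenly between platform-exclusive strata. The generic
    platform carries sense transcripts only, with ~``redundancy_generic``
    probesets per gene; the DSA carries one sense probeset per gene, an
    antisense probeset for every NAT partner of its genes, and an
    unassigned-orientation stratum sized to ``unassigned_fraction`` of its
    platform-specific content. Fills ``truth.common_probesets`` (probesets
    derived from transcripts present on both platforms) and
    ``truth.planted_sas_genes`` (genes with both orientations on the DSA).
    """
    if not transcripts:
        raise ValueError("transcripts must be nonempty")
    rng = stage_rng(config.seed, 1)
    by_gene: dict = {}
    for rec in transcripts:
        by_gene.setdefault(rec.gene_id, {})[rec.orientation] = rec
    genes = sorted(by_gene)
    n = len(genes)
    perm = rng.permutation(n)
    n_shared = int(round(config.shared_content_fraction * n))
    shared = {genes[i] for i in perm[:n_shared]}
    rest = [genes[i] for i in perm[n_shared:]]
    generic_only = set(rest[: len(rest) // 2])
    dsa_only = set(rest) - generic_only

    generic = PlatformDesign("generic")
    dsa = PlatformDesign("dsa")
    common: set = set()

    for gid in genes:
        sense = by_gene[gid]["sense"]
        if gid in shared or gid in generic_only:
            k = 1 + int(rng.poisson(max(config.redundancy_generic - 1.0, 0.0)))
            for j in range(k):
                pid = f"GEN_{sense.transcript_id}_{j + 1}"
                generic.probesets[pid] = ProbeSet(
                    pid, "generic", _draw_probes(rng, sense.sequence, config),
                    sense.transcript_id, gid, "sense",
                )
                generic.transcripts[sense.transcript_id] = sense
                if gid in shared:
                    common.add(pid)
        if gid in shared or gid in dsa_only:
            pid = f"DSA_S_{sense.transcript_id}"
            dsa.probesets[pid] = ProbeSet(
                pid, "dsa", _draw_probes(rng, sense.sequence, config),
                sense.transcript_id, gid, "sense",
            )
            dsa.transcripts[sense.transcript_id] = sense
            if gid in shared:
                common.add(pid)
            anti = by_gene[gid].get("antisense")
            if anti is not None:
                apid = f"DSA_A_{anti.transcript_id}"
                dsa.probesets[apid] = ProbeSet(
                    apid, "dsa", _draw_probes(rng, anti.sequence, config),
                    anti.transcript_id, gid, "antisense",
                )
                dsa.transcripts[anti.transcript_id] = anti
                truth.planted_sas_genes.add(gid)

    # unannotated stratum: fresh transcripts with no gene id, DSA-specific
    n_specific = sum(1 for pid in dsa.probesets if pid not in common)
    uf = config.unassigned_fraction
    n_un = int(round(uf / (1.0 - uf) * n_specific)) if uf > 0 else 0
    lo, hi = config.transcript_length_range
    last_end = max(r.end for r in transcripts)
    cursor = last_end + hi + 10
    for j in range(n_un):
        L = int(rng.integers(lo, hi + 1))
        tid = f"U{j + 1:04d}"
        rec = TranscriptRecord(
            tid, None, "unassigned", _random_seq(rng, L),
            "chr1", cursor, cursor + L, "+" if rng.random() < 0.5 else "-",
        )
        cursor += L + hi + 10
        pid = f"DSA_U_{tid}"
        dsa.probesets[pid] = ProbeSet(
            pid, "dsa", _draw_probes(rng, rec.sequence, config), tid, None, "unassigned"
        )
        dsa.transcripts[tid] = rec

    truth.common_probesets = common
    return generic, dsa


def make_invitro_design(n_reps: int = 3) -> pd.DataFrame:
    """Design table for the four in-vitro conditions x n_reps replicates."""
    rows = []
    for cond in INVITRO_CONDITIONS:
        for r in range(1, n_reps + 1):
            rows.append({"sample_id": f"{cond}_r{r}", "condition": cond, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def make_clinical_design(n_clinical: int = 28) -> pd.DataFrame:
    """Design table for the clinical cohort, response groups split evenly.

    The real cohort's CR/PR/SD/PD split is not published; a near-even
    round-robin assignment is used as a stand-in.
    """
    rows = [
        {"sample_id": f"S{i + 1:02d}", "response": RESPONSE_GROUPS[i % 4]}
        for i in range(n_clinical)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_expression(
    platform: PlatformDesign,
    design: pd.DataFrame,
    truth: GroundTruth,
    config: SyntheticConfig,
) -> ExpressionExperiment:
    """Simulate an expression + flag matrix for one platform and design.

    Log2 intensity = per-transcript baseline + planted effect (where the
    sample's condition/response group is affected) + N(0, noise_sd_log2).
    Flags threshold the linear intensity (P above ``detect_threshold_P``, M
    between the two thresholds, A below), then are corrupted independently
    at ``flag_flip_rate`` (a corrupted flag becomes one of the other two
    calls, uniformly). Deterministic for a fixed config seed.
    """
    if "condition" in design.columns:
        kind = "invitro"
        bad = set(design["condition"]) - set(INVITRO_CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
    elif "response" in design.columns:
        kind = "clinical"
        bad = set(design["response"]) - set(RESPONSE_GROUPS)
        if bad:
            raise ValueError(f"unknown response labels: {sorted(bad)}")
    else:
        raise ValueError("design table must have a 'condition' or 'response' column")

    rng = stage_rng(config.seed, 2, platform.name, kind)
    lo, hi = config.baseline_log2_range
    baseline = {
        tid: float(rng.uniform(lo, hi)) for tid in sorted(platform.transcripts)
    }

    pids = sorted(platform.probesets)
    samples = list(design.index)
    n_r, n_c = len(pids), len(samples)

    treated_effects = {}
    if kind == "invitro":
        for cmp_name, (_, treated) in COMPARISONS.items():
            treated_effects[treated] = truth.planted_effects.get(cmp_name, {})

    log2 = np.empty((n_r, n_c))
    for i, pid in enumerate(pids):
        tid = platform.probesets[pid].transcript_id
        base = baseline[tid]
        for j, sample in enumerate(samples):
            eff = 0.0
            if kind == "invitro":
                cond = design.at[sample, "condition"]
                eff = treated_effects.get(cond, {}).get(tid, 0.0)
            else:
                grp = design.at[sample, "response"]
                if truth.planted_clinical_group.get(tid) == grp:
                    eff = truth.planted_effects["clinical"][tid]
            log2[i, j] = base + eff
    if config.noise_sd_log2 > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd_log2, size=(n_r, n_c))
    linear = np.power(2.0, log2)

    flags = np.full((n_r, n_c), "A", dtype="U1")
    flags[linear >= config.detect_threshold_M] = "M"
    flags[linear >= config.detect_threshold_P] = "P"
    if config.flag_flip_rate > 0:
        flip = rng.random((n_r, n_c)) < config.flag_flip_rate
        pick = rng.integers(0, 2, size=(n_r, n_c))
        others = {"P": ("M", "A"), "M": ("P", "A"), "A": ("P", "M")}
        for i, j in zip(*np.nonzero(flip)):
            flags[i, j] = others[flags[i, j]][pick[i, j]]

    expr = pd.DataFrame(linear, index=pids, columns=samples)
    flag_df = pd.DataFrame(flags, index=pids, columns=samples)
    return ExpressionExperiment(expr, flag_df, design)


def make_pathways(
    gene_ids,
    seed: int,
    n_pathways: int = 25,
    size_range: tuple = (10, 60),
    enriched_genes=None,
    n_enriched: int = 3,
    enriched_mix: float = 0.7,
) -> dict:
    """Synthetic pathway gene sets (GMT-style dict) over the given genes.

    ``n_enriched`` pathways are biased to draw ``enriched_mix`` of their
    members from ``enriched_genes`` so that the enrichment screen has
    planted positives to find.
    """
    rng = stage_rng(seed, 3)
    genes = sorted(gene_ids)
    enriched = sorted(set(enriched_genes or []) & set(genes))
    db: dict = {}
    lo, hi = size_range
    for i in range(n_pathways):
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        if i < n_enriched and enriched:
            k_enr = min(len(enriched), int(round(enriched_mix * size)))
            members = set(rng.choice(enriched, size=k_enr, replace=False))
            pool = [g for g in genes if g not in members]
            members |= set(rng.choice(pool, size=size - len(members), replace=False))
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        db[f"pathway_{i + 1:02d}"] = members
    return db


# ---------------------------------------------------------------------------
# writers


def write_platform(outdir: Path, platform: PlatformDesign) -> list:
    """Write probes.fasta, fulllength.fasta and annotation.tsv for a platform."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe_recs = []
    for pid in sorted(platform.probesets):
        for k, probe in enumerate(platform.probesets[pid].probes, start=1):
            probe_recs.append(SeqRecord(Seq(probe), id=f"{pid}|probe{k}", description=""))
    SeqIO.write(probe_recs, outdir / "probes.fasta", "fasta")
    full_recs = [
        SeqRecord(Seq(platform.transcripts[tid].sequence), id=tid, description="")
        for tid in sorted(platform.transcripts)
    ]
    SeqIO.write(full_recs, outdir / "fulllength.fasta", "fasta")
    platform.annotation_frame().to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    return [outdir / "probes.fasta", outdir / "fulllength.fasta", outdir / "annotation.tsv"]


def write_experiment(outdir: Path, exp: ExpressionExperiment) -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.expression.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")
    exp.flags.to_csv(outdir / "flags.tsv", sep="\t")
    exp.design.to_csv(outdir / "design.tsv", sep="\t")
    return [outdir / "expression.tsv", outdir / "flags.tsv", outdir / "design.tsv"]


def write_loci_bed(path: Path, transcripts) -> Path:
    """BED6 of transcript loci (score column unused, set to 0)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in sorted(transcripts, key=lambda r: (r.chrom, r.start, r.transcript_id)):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.transcript_id}\t0\t{rec.strand}\n"
            )
    return path
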