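"""Sense:antisense (SAS) pair discovery and cis-NAT overlap classification.

Probesets are first restricted to those with a gene annotation, collapsed
to unique gene ids per orientation, and a gene represented in BOTH
orientations constitutes a SAS pair — evidence that sense and antisense
transcripts from the same locus are co-represented (or co-detected). With
genomic loci available the pair's cis-NAT geometry is classified as
head-to-head (5' ends overlap), tail-to-tail (3' ends overlap) or fully
overlapping (one transcript contained in the other), and per-pair
expression concordance is labelled by comparing mean intensities on the
log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up


@dataclass
class OrientationBreakdown:
    """Sense / antisense / unassigned counts with half-up rounded shares."""

    n_sense: int
    n_antisense: int
    n_unassigned: int
    decimals: int = 2

    @property
    def total(self) -> int:
        return self.n_sense + self.n_antisense + self.n_unassigned

    def percentages(self) -> dict:
        from .report import percent_breakdown

        return {
            "sense": percent_breakdown(self.n_sense, self.total, self.decimals),
            "antisense": percent_breakdown(self.n_antisense, self.total, self.decimals),
            "unassigned": percent_breakdown(self.n_unassigned, self.total, self.decimals),
        }


@dataclass
class SASPairTable:
    """Gene-level SAS membership: deduplicated counts and matched pairs."""

    pairs: set
    n_sense_genes: int
    n_antisense_genes: int
    #: gene id -> dict(sense_probeset, antisense_probeset, category, concordance)
    per_pair: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) > min(self.n_sense_genes, self.n_antisense_genes):
            raise ValueError("pairs cannot exceed either deduplicated gene count")


def orientation_breakdown(probesets, decimals: int = 2) -> OrientationBreakdown:
    """Count probesets per orientation ({sense, antisense, unassigned})."""
    counts = {"sense": 0, "antisense": 0, "unassigned": 0}
    for ps in probesets:
        orientation = ps.orientation if hasattr(ps, "orientation") else ps
        if orientation not in counts:
            raise ValueError(f"unknown orientation {orientation!r}")
        counts[orientation] += 1
    return OrientationBreakdown(
        counts["sense"], counts["antisense"], counts["unassigned"], decimals
    )


def dedupe_by_gene(probeset_ids, annotation: pd.DataFrame, orientation: str) -> tuple:
    """Unique gene ids among probesets of one orientation.

    `annotation` must have probeset_id / gene_id / orientation columns
    (gene_id empty or NaN = unannotated; such probesets are dropped and
    counted). Returns (gene id set, n_dropped).
    """
    ann = annotation.set_index("probeset_id") if "probeset_id" in annotation.columns else annotation
    genes = set()
    dropped = 0
    for pid in probeset_ids:
        if pid not in ann.index:
            dropped += 1
            continue
        row = ann.loc[pid]
        if row["orientation"] != orientation:
            continue
        gid = row["gene_id"]
        if gid is None or (isinstance(gid, float) and np.isnan(gid)) or gid == "":
            dropped += 1
            continue
        genes.add(gid)
    return genes, dropped


def find_sas_pairs(sense_genes, antisense_genes) -> SASPairTable:
    """Genes represented in both orientations = SAS pairs."""
    sense_genes, antisense_genes = set(sense_genes), set(antisense_genes)
    return SASPairTable(
        pairs=sense_genes & antisense_genes,
        n_sense_genes=len(sense_genes),
        n_antisense_genes=len(antisense_genes),
    )


def classify_overlap_category(sense_locus: tuple, antisense_locus: tuple) -> str:
    """cis-NAT overlap geometry of two opposite-strand loci.

    Loci are (chrom, start, end, strand), 0-based half-open. Containment
    (one interval holding the other, equality allowed) takes precedence as
    fully_overlapping; otherwise the overlap interval is inspected: holding
    both 5' ends gives head_to_head, both 3' ends tail_to_tail. Disjoint
    intervals are non_overlapping.
    """
    c1, s1, e1, st1 = sense_locus
    c2, s2, e2, st2 = antisense_locus
    if c1 != c2:
        return "non_overlapping"
    if st1 == st2:
        raise ValueError("overlap classification requires opposite strands")
    lo, hi = max(s1, s2), min(e1, e2)
    if lo >= hi:
        return "non_overlapping"
    if (s1 <= s2 and e2 <= e1) or (s2 <= s1 and e1 <= e2):
        return "fully_overlapping"

    def five_prime(start, end, strand):
        return start if strand == "+" else end - 1

    def three_prime(start, end, strand):
        return end - 1 if strand == "+" else start

    in_overlap = lambda pos: lo <= pos < hi
    if in_overlap(five_prime(s1, e1, st1)) and in_overlap(five_prime(s2, e2, st2)):
        return "head_to_head"
    if in_overlap(three_prime(s1, e1, st1)) and in_overlap(three_prime(s2, e2, st2)):
        return "tail_to_tail"
    # unreachable for opposite-strand overlapping intervals without
    # containment, kept for exhaustiveness
    return "non_overlapping"


def label_concordance(mean_sense: float, mean_antisense: float, tau: float = 1.0) -> str:
    """Concordant vs discordant intensity of a SAS pair.

    Discordant when |log2(mean_sense) - log2(mean_antisense)| strictly
    exceeds `tau` (default 1, i.e. a 2-fold difference is still concordant
    at the boundary). Means must be positive linear intensities.
    """
    if mean_sense <= 0 or mean_antisense <= 0:
        raise ValueError("means must be positive")
    delta = abs(np.log2(mean_sense) - np.log2(mean_antisense))
    return "discordant" if delta > tau else "concordant"


def annotate_pairs(
    table: SASPairTable,
    annotation: pd.DataFrame,
    loci: dict | None = None,
    expression_means: dict | None = None,
    tau: float = 1.0,
) -> SASPairTable:
    """Attach probeset representatives, overlap category and concordance.

    For each paired gene one sense and one antisense probeset are chosen as
    representatives — the one with the highest mean intensity when
    expression means are given, else the lexicographically smallest id.
    `loci` maps transcript_id -> (chrom, start, end, strand).
    """
    ann = annotation.set_index("probeset_id")
    for gid in sorted(table.pairs):
        entry = {}
        for orientation, key in (("sense", "sense_probeset"), ("antisense", "antisense_probeset")):
            rows = ann[(ann["gene_id"] == gid) & (ann["orientation"] == orientation)]
            pids = sorted(rows.index)
            if expression_means:
                pids.sort(key=lambda p: (-expression_means.get(p, float("-inf")), p))
            entry[key] = pids[0]
            entry[f"{orientation}_transcript"] = rows.loc[pids[0], "transcript_id"]
        if loci is not None:
            s_loc = loci.get(entry["sense_transcript"])
            a_loc = loci.get(entry["antisense_transcript"])
            if s_loc and a_loc:
                entry["category"] = classify_overlap_category(s_loc, a_loc)
        if expression_means:
            ms = expression_means.get(entry["sense_probeset"])
            ma = expression_means.get(entry["antisense_probeset"])
            if ms is not None and ma is not None:
                entry["concordance"] = label_concordance(ms, ma, tau)
        table.per_pair[gid] = entry
    return table


def cross_experiment_overlap(tables: dict) -> pd.DataFrame:
    """Pairwise intersections of gene-id sets per class across experiments.

    `tables` maps experiment name -> {"sense": set, "antisense": set,
    "sas_pairs": set}. Returns a long-format frame with one row per
    (experiment pair, class) holding the intersection size.
    """
    names = sorted(tables)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for cls in ("sense", "antisense", "sas_pairs"):
                inter = set(tables[a].get(cls, set())) & set(tables[b].get(cls, set()))
                rows.append(
                    {"experiment_a": a, "experiment_b": b, "class": cls, "n_common": len(inter)}
                )
    return pd.DataFrame(rows, columns=["experiment_a", "experiment_b", "class", "n_common"])


def pair_frame(table: SASPairTable) -> pd.DataFrame:
    rows = []
    for gid in sorted(table.pairs):
        e = table.per_pair.get(gid, {})
        rows.append(
            {
                "gene_id": gid,
                "sense_probeset": e.get("sense_probeset", ""),
                "antisense_probeset": e.get("antisense_probeset", ""),
                "category": e.get("category", ""),
                "concordance": e.get("concordance", ""),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "sense_probeset", "antisense_probeset", "category", "concordance"]
    )
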