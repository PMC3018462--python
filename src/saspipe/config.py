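"""Configuration objects for the synthetic-data generator and the filter cascades."""

from __future__ import annotations

from dataclasses import dataclass, field


OVERLAP_CATEGORIES = ("head_to_head", "tail_to_tail", "fully_overlapping")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic transcriptome / two-platform study design.

    The defaults emulate a scaled-down version of a paired generic vs
    disease-specific array comparison: a generic sense-only platform with
    per-gene probeset redundancy, a disease-specific platform carrying
    sense, antisense and a small unannotated stratum, triplicate in-vitro
    conditions (parental/resistant x untreated/treated) with planted fold
    changes, and a 28-sample clinical cohort with four response groups.

    Parameters
    ----------
    n_genes : number of genes in the toy transcriptome.
    nat_fraction : probability that a gene has a natural-antisense partner
        transcript on the opposite strand of the same locus.
    overlap_category_weights : probabilities over the cis-NAT overlap
        geometries (head-to-head / tail-to-tail / fully overlapping).
    transcript_length_range : (min, max) transcript length in nt, inclusive.
    probe_length : probe length in nt (25-mer oligos by default).
    probes_per_probeset : probes drawn per probeset (11 by default).
    shared_content_fraction : fraction of genes represented on both platforms.
    redundancy_generic : mean probesets per gene on the generic platform.
    unassigned_fraction : share of disease-specific probesets with no
        orientation annotation (structural realism of unannotated content).
    de_fraction : fraction of transcripts given a planted treatment effect.
    effect_log2 : planted |log2 fold change|.
    noise_sd_log2 : replicate noise SD on the log2 scale.
    baseline_log2_range : per-transcript basal log2 intensity range.
    detect_threshold_P, detect_threshold_M : linear-intensity thresholds for
        Present / Marginal flag calls (Absent below M).
    flag_flip_rate : probability that a flag call is corrupted to another.
    n_reps : replicates per in-vitro condition.
    n_clinical : clinical sample count (CR/PR/SD/PD groups, near-even split).
    seed : master seed; every stage derives its own stream from it.
    """

    n_genes: int = 500
    nat_fraction: float = 0.2
    overlap_category_weights: dict = field(
        default_factory=lambda: {
            "head_to_head": 0.4,
            "tail_to_tail": 0.4,
            "fully_overlapping": 0.2,
        }
    )
    transcript_length_range: tuple = (500, 2000)
    probe_length: int = 25
    probes_per_probeset: int = 11
    shared_content_fraction: float = 0.6
    redundancy_generic: float = 1.8
    unassigned_fraction: float = 0.09
    de_fraction: float = 0.06
    effect_log2: float = 1.0
    noise_sd_log2: float = 0.25
    baseline_log2_range: tuple = (4.0, 12.0)
    detect_threshold_P: float = 100.0
    detect_threshold_M: float = 50.0
    flag_flip_rate: float = 0.01
    n_reps: int = 3
    n_clinical: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nat_fraction",
            "shared_content_fraction",
            "unassigned_fraction",
            "de_fraction",
            "flag_flip_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        w = self.overlap_category_weights
        if set(w) != set(OVERLAP_CATEGORIES):
            raise ValueError(f"overlap_category_weights must have keys {OVERLAP_CATEGORIES}")
        if any(x < 0 for x in w.values()) or abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("overlap_category_weights must be nonnegative and sum to 1")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ValueError("transcript_length_range must satisfy 0 < min <= max")
        if self.probe_length > lo:
            raise ValueError(
                "probe_length exceeds minimum transcript length "
                f"({self.probe_length} > {lo})"
            )
        if not self.detect_threshold_M < self.detect_threshold_P:
            raise ValueError("detect_threshold_M must be below detect_threshold_P")
        if self.n_genes < 1 or self.n_reps < 1 or self.n_clinical < 1:
            raise ValueError("n_genes, n_reps and n_clinical must be positive")


@dataclass
class FilterConfig:
    """Detection + differential-expression filter settings.

    ``fold_threshold`` is inclusive (a probeset at exactly the threshold
    passes). ``detection_mode`` selects replicate-consistency detection
    (``all_replicates``, the in-vitro rule) or strict-majority detection
    (``majority``, the clinical rule: flagged P or M in > majority_fraction
    of all samples).
    """

    fold_threshold: float = 1.3
    p_threshold: float = 0.05
    detection_mode: str = "all_replicates"
    majority_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fold_threshold < 1.0:
            raise ValueError("fold_threshold must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.detection_mode not in ("all_replicates", "majority"):
            raise ValueError("detection_mode must be 'all_replicates' or 'majority'")
        if not 0.0 <= self.majority_fraction < 1.0:
            raise ValueError("majority_fraction must be in [0, 1)")


CLINICAL_FILTER = FilterConfig(fold_threshold=1.5, detection_mode="majority")
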