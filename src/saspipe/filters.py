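"""Detection and differential-expression filter cascades.

Two variants mirror the two study arms:

* **in-vitro** — a probeset is *detected* in a condition when its flag call
  is Present or Marginal in every replicate of that condition; it is
  *differentially expressed* between two conditions when it is detected in
  both, its linear-scale fold change is at least 1.3 (inclusive) and a
  two-sided pooled-variance Student t-test on log2 intensities gives
  p < 0.05. No multiple-testing correction is applied — the cascade is a
  faithful rendering of an era-standard raw-p filter, not a recommendation.
* **clinical** — detected when flagged P or M in strictly more than 50% of
  all samples; differentially expressed when, for at least one response
  group (CR/PR/SD/PD), the linear-scale fold change of that group's mean
  against the mean of all remaining samples is at least 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import FilterConfig

PRESENT_OR_MARGINAL = frozenset({"P", "M"})


@dataclass
class ExpressionExperiment:
    """Linear-scale expression matrix + flag matrix + design table.

    ``expression`` and ``flags`` are probesets x samples with identical
    labels; ``design`` is indexed by sample id and carries either a
    ``condition``/``replicate`` pair (in-vitro) or a ``response`` label
    (clinical).
    """

    expression: pd.DataFrame
    flags: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.flags.index) or not self.expression.columns.equals(
            self.flags.columns
        ):
            raise ValueError("expression and flags must share identical row/column labels")
        if set(self.expression.columns) != set(self.design.index):
            raise ValueError("design table samples must match expression columns")
        if (self.expression.to_numpy() <= 0).any():
            raise ValueError("intensities must be positive (linear scale)")
        bad = set(np.unique(self.flags.to_numpy())) - {"P", "M", "A"}
        if bad:
            raise ValueError(f"flags must be P/M/A, found {sorted(bad)}")

    def samples_for(self, condition: str) -> list:
        if "condition" not in self.design.columns:
            raise ValueError("experiment has no 'condition' column (clinical design?)")
        hit = self.design.index[self.design["condition"] == condition]
        if len(hit) == 0:
            raise ValueError(f"unknown condition label: {condition!r}")
        return list(hit)


@dataclass
class FilterCascadeResult:
    """Detected sets plus the nested DE subset with per-probeset statistics.

    ``detected`` maps a condition label (or "all" for clinical) to the
    detected probeset-id set. ``stats`` has one row per probeset that
    entered the DE test, with columns fold_change (>= 1), direction
    (up/down relative to the first/reference group), p_value and, where a
    degenerate zero-variance contrast occurred, degenerate=True. ``de`` is
    the set of probesets passing the full cascade.
    """

    detected: dict
    de: set
    stats: pd.DataFrame
    comparison: str = ""
    warnings: list = field(default_factory=list)


def detect_in_vitro(exp: ExpressionExperiment, condition: str) -> set:
    """Probesets flagged P or M in ALL replicates of `condition`."""
    cols = exp.samples_for(condition)
    sub = exp.flags[cols]
    ok = sub.isin(PRESENT_OR_MARGINAL).all(axis=1)
    return set(sub.index[ok])


def detect_clinical(exp: ExpressionExperiment, majority_fraction: float = 0.5) -> set:
    """Probesets flagged P or M in strictly more than `majority_fraction` of samples."""
    if exp.flags.shape[1] == 0:
        raise ValueError("experiment has no samples")
    frac = exp.flags.isin(PRESENT_OR_MARGINAL).sum(axis=1) / exp.flags.shape[1]
    return set(exp.flags.index[frac > majority_fraction])


def _fold_and_direction(mean_a: np.ndarray, mean_b: np.ndarray) -> tuple:
    """Direction-agnostic linear fold change (>=1) and up/down label (b vs a)."""
    with np.errstate(divide="ignore"):
        ratio = mean_b / mean_a
    fold = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio >= 1.0, "up", "down")
    return fold, direction


def de_filter(
    exp: ExpressionExperiment,
    condition_a: str,
    condition_b: str,
    cfg: FilterConfig | None = None,
) -> FilterCascadeResult:
    """In-vitro DE cascade for condition_b vs condition_a.

    Detection (P/M in all replicates of each condition) is applied first;
    only probesets detected in BOTH conditions enter the fold-change and
    t-test filters. The fold change is computed on linear-scale replicate
    means, direction-agnostically; the t-test is a pooled-variance
    two-sided Student test on log2 intensities. A probeset with zero
    variance in both groups and equal means gets fold 1 (excluded); zero
    variance with unequal means is flagged degenerate and treated as p=0.
    """
    cfg = cfg or FilterConfig()
    det_a = detect_in_vitro(exp, condition_a)
    det_b = detect_in_vitro(exp, condition_b)
    candidates = sorted(det_a & det_b)
    cols_a = exp.samples_for(condition_a)
    cols_b = exp.samples_for(condition_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("t-test requires >= 2 replicates per condition")

    xa = exp.expression.loc[candidates, cols_a].to_numpy(float)
    xb = exp.expression.loc[candidates, cols_b].to_numpy(float)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    fold, direction = _fold_and_direction(mean_a, mean_b)

    la, lb = np.log2(xa), np.log2(xb)
    res = stats.ttest_ind(lb, la, axis=1, equal_var=True)
    pvals = np.asarray(res.pvalue, float)
    # identical replicates within both groups (exact, on the raw values)
    zero_var = (np.ptp(xa, axis=1) == 0) & (np.ptp(xb, axis=1) == 0)
    degenerate = zero_var & (mean_a != mean_b)
    pvals = np.where(degenerate, 0.0, pvals)
    pvals = np.where(zero_var & (mean_a == mean_b), 1.0, pvals)

    table = pd.DataFrame(
        {
            "fold_change": fold,
            "direction": direction,
            "p_value": pvals,
            "degenerate": degenerate,
        },
        index=pd.Index(candidates, name="probeset_id"),
    )
    passing = set(table.index[(table["fold_change"] >= cfg.fold_threshold) & (table["p_value"] < cfg.p_threshold)])
    warnings = []
    if degenerate.any():
        warnings.append(f"{int(degenerate.sum())} probesets had zero variance with unequal means (p set to 0)")
    return FilterCascadeResult(
        detected={condition_a: det_a, condition_b: det_b},
        de=passing,
        stats=table,
        comparison=f"{condition_b}_vs_{condition_a}",
        warnings=warnings,
    )


def de_filter_clinical(exp: ExpressionExperiment, cfg: FilterConfig | None = None) -> FilterCascadeResult:
    """Clinical DE cascade: strict-majority detection, then one-vs-rest fold.

    For each response group g the linear fold change of mean(g) against
    mean(all other samples) is computed; a detected probeset passes when
    the fold is at least ``cfg.fold_threshold`` (default 1.5) for at least
    one group. Empty groups are skipped with a warning.
    """
    from .config import CLINICAL_FILTER

    cfg = cfg or CLINICAL_FILTER
    if "response" not in exp.design.columns:
        raise ValueError("clinical cascade needs a 'response' design column")
    detected = detect_clinical(exp, cfg.majority_fraction)
    candidates = sorted(detected)
    groups = sorted(set(exp.design["response"]))
    if len(groups) < 2:
        raise ValueError("clinical DE filter needs >= 2 response groups")

    warnings = []
    best_fold = np.zeros(len(candidates))
    best_group = np.array([""] * len(candidates), dtype=object)
    best_dir = np.array([""] * len(candidates), dtype=object)
    x = exp.expression.loc[candidates].to_numpy(float)
    sample_groups = exp.design.loc[exp.expression.columns, "response"].to_numpy()
    for g in groups:
        in_g = sample_groups == g
        if in_g.sum() == 0:
            warnings.append(f"response group {g} has no samples; skipped")
            continue
        if (~in_g).sum() == 0:
            warnings.append(f"response group {g} covers all samples; skipped")
            continue
        mean_g = x[:, in_g].mean(axis=1)
        mean_rest = x[:, ~in_g].mean(axis=1)
        fold, direction = _fold_and_direction(mean_rest, mean_g)
        better = fold > best_fold
        best_fold = np.where(better, fold, best_fold)
        best_group = np.where(better, g, best_group)
        best_dir = np.where(better, direction, best_dir)

    table = pd.DataFrame(
        {"fold_change": best_fold, "direction": best_dir, "best_group": best_group},
        index=pd.Index(candidates, name="probeset_id"),
    )
    passing = set(table.index[table["fold_change"] >= cfg.fold_threshold])
    return FilterCascadeResult(
        detected={"all": detected},
        de=passing,
        stats=table,
        comparison="clinical_one_vs_rest",
        warnings=warnings,
    )
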