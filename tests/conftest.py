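import numpy as np
import pandas as pd
import pytest

from saspipe.config import SyntheticConfig
from saspipe.filters import ExpressionExperiment
from saspipe.simulate import (
    design_platforms,
    generate_transcriptome,
    make_clinical_design,
    make_invitro_design,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_world():
    """A small default-parameter synthetic study (transcripts, truth, platforms)."""
    cfg = SyntheticConfig(n_genes=60, seed=1)
    transcripts, truth = generate_transcriptome(cfg)
    generic, dsa = design_platforms(transcripts, cfg, truth)
    return cfg, transcripts, truth, generic, dsa


@pytest.fixture(scope="session")
def noiseless_world():
    """Noiseless, well-expressed study: every probeset flagged P, no flag flips."""
    cfg = SyntheticConfig(
        n_genes=80,
        seed=2,
        noise_sd_log2=0.0,
        flag_flip_rate=0.0,
        baseline_log2_range=(8.0, 12.0),
    )
    transcripts, truth = generate_transcriptome(cfg)
    generic, dsa = design_platforms(transcripts, cfg, truth)
    invitro = simulate_expression(dsa, make_invitro_design(cfg.n_reps), truth, cfg)
    clinical = simulate_expression(dsa, make_clinical_design(cfg.n_clinical), truth, cfg)
    return cfg, transcripts, truth, generic, dsa, invitro, clinical


def make_invitro_experiment(expr_rows, flag_rows, conditions=("ctrl", "trt"), n_reps=3):
    """Hand-built in-vitro ExpressionExperiment from per-probeset row dicts.

    `expr_rows` / `flag_rows` map probeset id -> list of values ordered as
    condition-major, replicate-minor.
    """
    samples, design_rows = [], []
    for cond in conditions:
        for r in range(1, n_reps + 1):
            samples.append(f"{cond}_r{r}")
            design_rows.append({"sample_id": f"{cond}_r{r}", "condition": cond, "replicate": r})
    design = pd.DataFrame(design_rows).set_index("sample_id")
    expr = pd.DataFrame.from_dict(expr_rows, orient="index", columns=samples).astype(float)
    flags = pd.DataFrame.from_dict(flag_rows, orient="index", columns=samples)
    return ExpressionExperiment(expr, flags, design)


def make_clinical_experiment(expr_rows, flag_rows, responses):
    samples = [f"S{i + 1:02d}" for i in range(len(responses))]
    design = pd.DataFrame({"sample_id": samples, "response": list(responses)}).set_index("sample_id")
    expr = pd.DataFrame.from_dict(expr_rows, orient="index", columns=samples).astype(float)
    flags = pd.DataFrame.from_dict(flag_rows, orient="index", columns=samples)
    return ExpressionExperiment(expr, flags, design)


def naive_match_counts(probes, sequences):
    """Brute-force per-target probe-occurrence counts (both strands)."""
    from saspipe._util import revcomp

    counts = {}
    for sid, seq in sequences.items():
        c = 0
        for p in probes:
            if p in seq or revcomp(p) in seq:
                c += 1
        if c:
            counts[sid] = c
    return counts


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
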