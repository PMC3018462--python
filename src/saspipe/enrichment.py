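"""Hypergeometric over-representation of pathways among DE genes.

Probesets are collapsed to unique gene ids first (a platform commonly holds
several probesets per gene), the gene universe is the annotated gene set of
the platform under test, and each pathway with a DE-overlap strictly above
a per-pathway gene-count cutoff is scored with the upper-tail
hypergeometric probability P(X >= k). Raw p-values are reported without
multiple-testing correction, matching the screening style this pipeline
reproduces; this is documented, not endorsed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from scipy import stats


@dataclass
class EnrichmentResult:
    """One pathway's contingency counts and upper-tail probability.

    N = annotated genes in the universe, K = pathway genes in the universe,
    n = selected (DE) genes in the universe, k = selected genes in the
    pathway.
    """

    pathway: str
    n_universe: int
    n_pathway: int
    n_selected: int
    n_overlap: int
    p_value: float
    significant: bool = False


def read_gmt(path: Path) -> dict:
    """Parse a GMT gene-set file: name <tab> description <tab> gene...

    Returns {pathway name: set of gene ids}. Duplicate names are an error.
    """
    db: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, genes = parts[0], {g for g in parts[2:] if g}
            if name in db:
                raise ValueError(f"duplicate pathway name: {name}")
            if not genes:
                raise ValueError(f"empty gene set: {name}")
            db[name] = genes
    return db


def write_gmt(path: Path, db: dict) -> Path:
    with open(path, "w") as fh:
        for name in sorted(db):
            fh.write("\t".join([name, "synthetic"] + sorted(db[name])) + "\n")
    return Path(path)


def collapse_to_genes(probeset_ids, annotation: dict) -> tuple:
    """Collapse probesets to unique gene ids; drop unannotated ones.

    `annotation` maps probeset id -> gene id (missing / None / "" counts as
    unannotated). Returns (gene id set, n_dropped).
    """
    genes = set()
    dropped = 0
    for pid in probeset_ids:
        gid = annotation.get(pid)
        if gid:
            genes.add(gid)
        else:
            dropped += 1
    return genes, dropped


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space.

    N = population size, K = marked items, n = draws, k = observed marked
    draws. k = 0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    de_genes,
    platform_genes,
    db: dict,
    min_genes: int = 15,
    alpha: float = 0.05,
) -> list:
    """Score every eligible pathway; sort by ascending p-value.

    The universe is restricted to platform genes with pathway annotation
    (genes appearing in at least one set of `db`). Pathways are eligible
    when their DE-overlap count is STRICTLY greater than `min_genes`
    ("greater than 15 genes per pathway" is a strict cutoff). Results with
    p < alpha are flagged significant. An empty DE set yields an empty list.
    """
    de_genes = set(de_genes)
    platform_genes = set(platform_genes)
    if not de_genes <= platform_genes:
        raise ValueError("de_genes must be a subset of platform_genes")
    if not de_genes:
        return []
    annotated = set().union(*db.values()) if db else set()
    universe = platform_genes & annotated
    selected = de_genes & universe
    results = []
    for name in sorted(db):
        pathway_genes = db[name] & universe
        overlap = selected & pathway_genes
        if len(overlap) <= min_genes:
            continue
        p = hypergeom_upper_tail(len(universe), len(pathway_genes), len(selected), len(overlap))
        results.append(
            EnrichmentResult(
                pathway=name,
                n_universe=len(universe),
                n_pathway=len(pathway_genes),
                n_selected=len(selected),
                n_overlap=len(overlap),
                p_value=p,
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def enrichment_frame(results) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "N": r.n_universe,
                "K": r.n_pathway,
                "n": r.n_selected,
                "k": r.n_overlap,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["pathway", "N", "K", "n", "k", "p_value", "significant"],
    )
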