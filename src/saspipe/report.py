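"""Pipeline orchestration and study-style summary tables.

`run_full_pipeline` executes the whole synthetic study end to end:
simulate -> cross-platform content mapping -> detection/DE filter cascades
(sensitive, resistant, clinical) -> pathway enrichment -> sense:antisense
discovery -> array-vs-qPCR concordance, writing every table plus a run
manifest with content digests. All randomness derives from the single
config seed, so two runs with the same config produce byte-identical
bundles.

All reported percentages use half-up rounding at a fixed precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import round_half_up, sha256_file, stage_rng
from .concordance import concordance_from_pairs
from .config import CLINICAL_FILTER, FilterConfig, SyntheticConfig
from .enrichment import collapse_to_genes, enrich, enrichment_frame, write_gmt
from .filters import de_filter, de_filter_clinical, detect_in_vitro
from .mapping import classify_common_unique, partition_frame
from .sas import (
    annotate_pairs,
    cross_experiment_overlap,
    dedupe_by_gene,
    find_sas_pairs,
    orientation_breakdown,
    pair_frame,
)
from .simulate import (
    COMPARISONS,
    design_platforms,
    generate_transcriptome,
    make_clinical_design,
    make_invitro_design,
    make_pathways,
    simulate_expression,
    write_experiment,
    write_loci_bed,
    write_platform,
)


def percent_breakdown(count: int, total: int, decimals: int = 2) -> str:
    """Render 100*count/total as a half-up rounded percentage string."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must satisfy 0 <= count <= total")
    value = round_half_up(100.0 * count / total, decimals)
    return f"{value:.{decimals}f}%"


@dataclass
class PipelineConfig:
    """Everything `run_full_pipeline` needs.

    The enrichment gene-per-pathway cutoffs are scaled to the synthetic
    experiment size (the screening rule fixes the cutoff relative to the
    number of genes in the experiment, so desk-scale runs use small
    values).
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    invitro_filter: FilterConfig = field(default_factory=FilterConfig)
    clinical_filter: FilterConfig = field(default_factory=lambda: FilterConfig(
        fold_threshold=1.5, detection_mode="majority"
    ))
    min_genes_per_pathway: int = 2
    enrichment_alpha: float = 0.05
    n_pathways: int = 25
    concordance_genes: int = 13
    qpcr_noise_sd_log2: float = 0.3
    concordance_tau: float = 1.0
    include_clinical: bool = True
    outdir: Path = Path("saspipe_out")

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SyntheticConfig(**raw.pop("synthetic", {}))
        invitro = FilterConfig(**raw.pop("invitro_filter", {}))
        clin_kwargs = {"fold_threshold": 1.5, "detection_mode": "majority"}
        clin_kwargs.update(raw.pop("clinical_filter", {}))
        clinical = FilterConfig(**clin_kwargs)
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        return cls(synthetic=synth, invitro_filter=invitro, clinical_filter=clinical, **raw)


def _write_ids(path: Path, ids) -> Path:
    with open(path, "w") as fh:
        for pid in sorted(ids):
            fh.write(pid + "\n")
    return path


def _de_table(result) -> pd.DataFrame:
    tab = result.stats.copy()
    tab.insert(0, "comparison", result.comparison)
    tab["passes"] = tab.index.isin(result.de)
    return tab


def _experiment_detected(exp, comparison: str) -> set:
    """Probesets detected in at least one condition of an in-vitro comparison."""
    cond_a, cond_b = COMPARISONS[comparison]
    return detect_in_vitro(exp, cond_a) | detect_in_vitro(exp, cond_b)


def _sas_class_sets(probeset_ids, annotation: pd.DataFrame) -> dict:
    sense, _ = dedupe_by_gene(probeset_ids, annotation, "sense")
    antisense, _ = dedupe_by_gene(probeset_ids, annotation, "antisense")
    table = find_sas_pairs(sense, antisense)
    return {"sense": sense, "antisense": antisense, "sas_pairs": table.pairs, "table": table}


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate -> map -> filter -> enrich -> sas -> concordance.

    Returns a report dict (also serialized to `outdir`); every emitted file
    appears in manifest.json with its SHA-256 digest.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list = []
    report: dict = {"seed": cfg.synthetic.seed, "version": __version__}

    def _stage(name):
        def fail(exc):
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return fail

    # --- simulate -----------------------------------------------------------
    try:
        transcripts, truth = generate_transcriptome(cfg.synthetic)
        generic, dsa = design_platforms(transcripts, cfg.synthetic, truth)
        all_transcripts = {t.transcript_id: t for t in transcripts}
        all_transcripts.update(dsa.transcripts)
        invitro_design = make_invitro_design(cfg.synthetic.n_reps)
        experiments = {
            "invitro_generic": simulate_expression(generic, invitro_design, truth, cfg.synthetic),
            "invitro_dsa": simulate_expression(dsa, invitro_design, truth, cfg.synthetic),
        }
        if cfg.include_clinical:
            clinical_design = make_clinical_design(cfg.synthetic.n_clinical)
            experiments["clinical_dsa"] = simulate_expression(
                dsa, clinical_design, truth, cfg.synthetic
            )
        for platform in (generic, dsa):
            written += write_platform(out / "platforms" / platform.name, platform)
        for name, exp in experiments.items():
            written += write_experiment(out / "expression" / name, exp)
        truth_path = out / "truth.json"
        truth_path.write_text(truth.to_json())
        written.append(truth_path)
        written.append(write_loci_bed(out / "loci.bed", all_transcripts.values()))
    except Exception as exc:  # noqa: BLE001
        _stage("simulate")(exc)

    # --- map ----------------------------------------------------------------
    try:
        partition = classify_common_unique(generic, dsa)
        map_dir = out / "mapping"
        map_dir.mkdir(exist_ok=True)
        partition_frame(partition).to_csv(map_dir / "partition.tsv", sep="\t", index=False)
        written.append(map_dir / "partition.tsv")
        summary = partition.summary()
        summary_frame = pd.DataFrame(summary).T[["total", "common", "unique", "excluded"]]
        summary_frame.index.name = "platform"
        summary_frame.to_csv(map_dir / "content_summary.tsv", sep="\t")
        written.append(map_dir / "content_summary.tsv")
        report["mapping"] = summary
    except Exception as exc:  # noqa: BLE001
        _stage("map")(exc)

    # --- filter -------------------------------------------------------------
    filter_results: dict = {}
    try:
        filt_dir = out / "filters"
        filt_dir.mkdir(exist_ok=True)
        counts: dict = {}
        for exp_name in ("invitro_generic", "invitro_dsa"):
            exp = experiments[exp_name]
            for comparison, (cond_a, cond_b) in COMPARISONS.items():
                res = de_filter(exp, cond_a, cond_b, cfg.invitro_filter)
                filter_results[(exp_name, comparison)] = res
                tag = f"{exp_name}_{comparison}"
                written.append(
                    _write_ids(filt_dir / f"detected_{tag}.txt", res.detected[cond_a] & res.detected[cond_b])
                )
                _de_table(res).to_csv(filt_dir / f"de_table_{tag}.tsv", sep="\t", float_format="%.6g")
                written.append(filt_dir / f"de_table_{tag}.tsv")
                counts[tag] = {
                    "detected_" + cond_a: len(res.detected[cond_a]),
                    "detected_" + cond_b: len(res.detected[cond_b]),
                    "de": len(res.de),
                }
        if cfg.include_clinical:
            res = de_filter_clinical(experiments["clinical_dsa"], cfg.clinical_filter)
            filter_results[("clinical_dsa", "clinical")] = res
            written.append(_write_ids(filt_dir / "detected_clinical_dsa.txt", res.detected["all"]))
            _de_table(res).to_csv(filt_dir / "de_table_clinical_dsa.tsv", sep="\t", float_format="%.6g")
            written.append(filt_dir / "de_table_clinical_dsa.tsv")
            counts["clinical_dsa"] = {"detected": len(res.detected["all"]), "de": len(res.de)}
        summary = pd.DataFrame(counts).T
        summary.index.name = "experiment"
        summary.to_csv(filt_dir / "filter_summary.tsv", sep="\t")
        written.append(filt_dir / "filter_summary.tsv")
        report["filters"] = counts
    except Exception as exc:  # noqa: BLE001
        _stage("filter")(exc)

    # --- enrich -------------------------------------------------------------
    try:
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        dsa_ann = {
            ps.probeset_id: ps.gene_id for ps in dsa.probesets.values() if ps.gene_id
        }
        platform_genes = set(dsa_ann.values())
        de_genes_sens, _ = collapse_to_genes(
            filter_results[("invitro_dsa", "sensitive")].de, dsa_ann
        )
        db = make_pathways(
            platform_genes,
            cfg.synthetic.seed,
            n_pathways=cfg.n_pathways,
            enriched_genes=de_genes_sens,
        )
        written.append(write_gmt(enr_dir / "pathways.gmt", db))
        report["enrichment"] = {}
        for comparison, min_genes in (
            ("sensitive", cfg.min_genes_per_pathway),
            ("resistant", cfg.min_genes_per_pathway),
        ):
            de_genes, _ = collapse_to_genes(
                filter_results[("invitro_dsa", comparison)].de, dsa_ann
            )
            results = enrich(de_genes, platform_genes, db, min_genes, cfg.enrichment_alpha)
            frame = enrichment_frame(results)
            frame.to_csv(enr_dir / f"enrichment_{comparison}.tsv", sep="\t", index=False, float_format="%.6g")
            written.append(enr_dir / f"enrichment_{comparison}.tsv")
            report["enrichment"][comparison] = {
                "tested": len(results),
                "significant": sum(r.significant for r in results),
            }
    except Exception as exc:  # noqa: BLE001
        _stage("enrich")(exc)

    # --- sas ----------------------------------------------------------------
    try:
        sas_dir = out / "sas"
        sas_dir.mkdir(exist_ok=True)
        annotation = dsa.annotation_frame()
        dsa_unique = partition.classes["dsa"]["unique"]
        loci = {tid: t.locus for tid, t in dsa.transcripts.items()}
        unique_ann = annotation[annotation["probeset_id"].isin(dsa_unique)]

        breakdown_rows = []
        strata: dict = {"all": dsa_unique}
        for comparison in COMPARISONS:
            res = filter_results[("invitro_dsa", comparison)]
            detected = _experiment_detected(experiments["invitro_dsa"], comparison) & dsa_unique
            strata[f"{comparison}_detected"] = detected
            strata[f"{comparison}_detected_de"] = res.de & dsa_unique
        if cfg.include_clinical:
            res = filter_results[("clinical_dsa", "clinical")]
            strata["clinical_detected"] = res.detected["all"] & dsa_unique
            strata["clinical_detected_de"] = res.de & dsa_unique

        orientation_of = dict(zip(annotation["probeset_id"], annotation["orientation"]))
        for name, ids in strata.items():
            bd = orientation_breakdown([orientation_of[p] for p in ids])
            pct = bd.percentages() if bd.total else {"sense": "", "antisense": "", "unassigned": ""}
            breakdown_rows.append(
                {
                    "stratum": name,
                    "sense": bd.n_sense,
                    "antisense": bd.n_antisense,
                    "unassigned": bd.n_unassigned,
                    "sense_pct": pct["sense"],
                    "antisense_pct": pct["antisense"],
                    "unassigned_pct": pct["unassigned"],
                }
            )
        pd.DataFrame(breakdown_rows).to_csv(
            sas_dir / "orientation_breakdown.tsv", sep="\t", index=False
        )
        written.append(sas_dir / "orientation_breakdown.tsv")

        mean_expr = experiments["invitro_dsa"].expression.mean(axis=1).to_dict()
        sas_tables: dict = {}
        sas_counts: dict = {}
        for name, ids in strata.items():
            sets = _sas_class_sets(ids, unique_ann)
            sas_tables[name] = sets
            sas_counts[name] = {
                "sense_genes": len(sets["sense"]),
                "antisense_genes": len(sets["antisense"]),
                "sas_pairs": len(sets["sas_pairs"]),
            }
        table_all = annotate_pairs(
            sas_tables["all"]["table"], unique_ann, loci, mean_expr, cfg.concordance_tau
        )
        pair_frame(table_all).to_csv(sas_dir / "sas_pairs.tsv", sep="\t", index=False)
        written.append(sas_dir / "sas_pairs.tsv")
        overlap_inputs = {
            name: {k: sas_tables[name][k] for k in ("sense", "antisense", "sas_pairs")}
            for name in sas_tables
            if name.endswith("_detected")
        }
        if len(overlap_inputs) >= 2:
            cross_experiment_overlap(overlap_inputs).to_csv(
                sas_dir / "overlap_matrix.tsv", sep="\t", index=False
            )
            written.append(sas_dir / "overlap_matrix.tsv")
        report["sas"] = sas_counts
    except Exception as exc:  # noqa: BLE001
        _stage("sas")(exc)

    # --- concordance --------------------------------------------------------
    try:
        conc_dir = out / "concordance"
        conc_dir.mkdir(exist_ok=True)
        res = filter_results[("invitro_dsa", "sensitive")]
        stats = res.stats.loc[sorted(res.de)].sort_values("fold_change", ascending=False)
        chosen = stats.head(cfg.concordance_genes)
        if len(chosen) < 3:
            raise ValueError(
                f"only {len(chosen)} DE probesets available; need >= 3 for a correlation"
            )
        signed = np.where(chosen["direction"] == "up", chosen["fold_change"], -chosen["fold_change"])
        rng = stage_rng(cfg.synthetic.seed, 4)
        log_arr = np.sign(signed) * np.log2(np.abs(signed))
        log_qpcr = log_arr + rng.normal(0.0, cfg.qpcr_noise_sd_log2, size=len(signed))
        qpcr = np.sign(log_qpcr) * np.power(2.0, np.abs(log_qpcr))
        pairs = pd.DataFrame(
            {"probeset_id": chosen.index, "array_fold": signed, "qpcr_fold": qpcr}
        )
        pairs.to_csv(conc_dir / "pairs.tsv", sep="\t", index=False, float_format="%.6g")
        written.append(conc_dir / "pairs.tsv")
        corr = concordance_from_pairs(pairs["array_fold"], pairs["qpcr_fold"])
        corr_payload = {
            "r": corr.r,
            "r_squared": corr.r_squared,
            "p_value": corr.p_value,
            "n": corr.n,
        }
        (conc_dir / "correlation.json").write_text(json.dumps(corr_payload, indent=1, sort_keys=True))
        written.append(conc_dir / "correlation.json")
        report["concordance"] = corr_payload
    except Exception as exc:  # noqa: BLE001
        _stage("concordance")(exc)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": cfg.synthetic.seed,
        "parameters": {
            "synthetic": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg.synthetic).items()},
            "invitro_filter": vars(cfg.invitro_filter),
            "clinical_filter": vars(cfg.clinical_filter),
            "min_genes_per_pathway": cfg.min_genes_per_pathway,
            "include_clinical": cfg.include_clinical,
        },
        "files": {
            str(Path(p).relative_to(out)): sha256_file(Path(p)) for p in sorted(map(str, written))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    report["manifest"] = manifest["files"]
    return report
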