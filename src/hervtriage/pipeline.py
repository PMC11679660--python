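"""End-to-end orchestration: simulate -> regions -> ancestry -> association -> triage -> poly(A).

A single structured configuration drives every stage; outputs are
tab-delimited tables plus VCF/BED/FASTA artifacts and a manifest of
SHA-256 content hashes, so a rerun with the same config and seed is
byte-identical. Stage counts (regions selected, variants tested,
exclusions by code) are logged and returned.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .ancestry import ancestry_covariates, estimate_admixture
from .association import significance_threshold, test_variant
from .cohort import allele_frequency, merge_cohorts, stratified_split
from .regions import filter_de_cpgs, merge_regions, select_near
from .retroelements import polya_extension
from .simulate import (
    SimulationConfig,
    aim_variant_frame,
    simulate_annotations,
    simulate_cohort,
    simulate_panel,
    simulate_retro_sequences,
)
from .triage import (
    CODE_SYMBOLS,
    TriageConfig,
    VariantSummary,
    confirm_variants,
    linkage_clusters,
    triage_variants,
)

log = logging.getLogger(__name__)

ASCII_CODES = {
    "dagger_inconsistent_maf": "dagger",
    "ddagger_crossed_pattern": "ddagger",
    "diamond_db_discrepancy": "diamond",
}


@dataclass
class PipelineConfig:
    output_dir: str = "pipeline_out"
    seed: int = 1
    alpha: float = 0.05
    radius_bp: int = 20_000
    split_trials: int = 10
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        tri = TriageConfig(**raw.pop("triage", {}))
        cfg = cls(simulation=sim, triage=tri, **raw)
        cfg.simulation.seed = raw.get("seed", cfg.seed) if sim.seed == 0 else sim.seed
        return cfg

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.radius_bp < 0:
            raise ValueError("radius_bp must be non-negative")


@dataclass
class PipelineResult:
    manifest: dict
    counts: dict
    triage_table: pd.DataFrame
    rare_table: pd.DataFrame
    polya_table: pd.DataFrame


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in dependency order on synthetic inputs."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    sim = config.simulation

    # --- simulate ---------------------------------------------------------
    panel = simulate_panel(sim)
    genes, elements = simulate_annotations(sim)
    cohort = simulate_cohort(panel, sim)
    sequences, alus, polya_truth = simulate_retro_sequences(sim)
    hio.write_panel(out / "panel.tsv", panel)
    hio.write_fasta(out / "alu.fasta", sequences)

    # --- regions ----------------------------------------------------------
    gene_frame = hio.gene_records_to_frame(genes)
    de_frame = filter_de_cpgs(gene_frame)
    de_genes = [g for g in genes if g.symbol in set(de_frame["gene"])]
    annotations = select_near(elements, de_genes, config.radius_bp)
    merged = merge_regions([a.element for a in annotations])
    hio.write_bed(out / "target_regions.bed", merged)
    ann_frame = pd.DataFrame(
        {
            "chrom": [a.element.chrom for a in annotations],
            "start": [a.element.start for a in annotations],
            "end": [a.element.end for a in annotations],
            "family": [a.family for a in annotations],
            "element_type": [a.element_type for a in annotations],
            "gene": [a.gene for a in annotations],
            "relation": [a.relation for a in annotations],
            "distance": [a.distance for a in annotations],
        }
    )
    ann_frame.to_csv(out / "herv_annotations.tsv", sep="\t", index=False)
    counts["genes_de"] = len(de_genes)
    counts["elements_selected"] = len(annotations)
    counts["regions_merged"] = len(merged)

    # --- cohort I/O -------------------------------------------------------
    for name, gm in (
        ("cases_blood", cohort.cases_blood),
        ("cases_tumor", cohort.cases_tumor),
        ("controls", cohort.controls),
    ):
        hio.write_vcf(out / f"{name}.vcf", gm.variants, gm.genotypes,
                      list(gm.samples.index))
    aim_variants = aim_variant_frame(panel)
    for name, geno, ids in (
        ("aims_cases", cohort.aim_genotypes_cases,
         list(cohort.cases_blood.samples.index)),
        ("aims_controls", cohort.aim_genotypes_controls,
         list(cohort.controls.samples.index)),
    ):
        hio.write_vcf(out / f"{name}.vcf", aim_variants, geno, ids)
    meta = pd.concat([cohort.cases_blood.samples, cohort.controls.samples])
    hio.write_metadata(out / "metadata.tsv", meta)

    # --- ancestry ---------------------------------------------------------
    aims = np.vstack(
        [cohort.aim_genotypes_cases, cohort.aim_genotypes_controls]
    )
    profiles = estimate_admixture(aims, panel)
    q_hat = np.stack([p.q for p in profiles])
    labels = [p.label for p in profiles]
    sample_ids = list(cohort.cases_blood.samples.index) + list(
        cohort.controls.samples.index
    )
    anc = pd.DataFrame(q_hat, columns=[f"q_{p}" for p in panel.populations],
                       index=pd.Index(sample_ids, name="sample_id"))
    anc["label"] = labels
    anc["loglik"] = [p.log_likelihood for p in profiles]
    anc["n_iter"] = [p.n_iterations for p in profiles]
    anc.to_csv(out / "ancestry.tsv", sep="\t")
    counts["samples_ancestry"] = len(anc)

    # --- split ------------------------------------------------------------
    meta = meta.copy()
    meta["ancestry_label"] = anc.loc[meta.index, "label"]
    case_ids = meta.index[meta["cohort"] == "case"]
    ctrl_ids = meta.index[meta["cohort"] == "control"]
    split_cases = stratified_split(
        meta.loc[case_ids], ["sex", "ancestry_label"],
        n_trials=config.split_trials, seed=config.seed,
    )
    split_ctrls = stratified_split(
        meta.loc[ctrl_ids], ["sex", "ancestry_label"],
        n_trials=config.split_trials, seed=config.seed + 1,
    )
    sets = {
        "training": set(split_cases.training) | set(split_ctrls.training),
        "validation": set(split_cases.validation) | set(split_ctrls.validation),
    }
    counts["training_cases"] = len(split_cases.training)
    counts["validation_cases"] = len(split_cases.validation)

    # --- association ------------------------------------------------------
    thresh = significance_threshold(config.alpha, sim.n_variants)
    covariates = ancestry_covariates(q_hat, panel.populations)
    cov_by_sample = covariates.set_index(pd.Index(sample_ids))
    merged_by_type = {
        "blood": merge_cohorts(cohort.cases_blood, cohort.controls),
        "tumor": merge_cohorts(cohort.cases_tumor, cohort.controls),
    }
    results: dict = {}
    assoc_rows = []
    for stype, gm in merged_by_type.items():
        pheno_all = (gm.samples["cohort"] == "case").to_numpy(float)
        sex_all = gm.samples["sex"].to_numpy(float)
        cov_all = cov_by_sample.loc[gm.samples.index].to_numpy(float)
        for set_name, ids in sets.items():
            mask = gm.samples.index.isin(ids)
            cell: dict = {}
            for j in range(gm.n_variants):
                key = tuple(gm.variants.iloc[j][["chrom", "pos", "ref", "alt"]])
                res = test_variant(
                    gm.genotypes[mask, j], pheno_all[mask], sex_all[mask],
                    cov_all[mask], variant_key=key,
                    threshold=thresh.threshold,
                )
                cell[key] = res
                assoc_rows.append(
                    {
                        "set": set_name, "sample_type": stype,
                        "chrom": key[0], "pos": key[1], "ref": key[2],
                        "alt": key[3], "n": res.n_used,
                        "beta_unadj": res.beta_unadj, "p_unadj": res.p_unadj,
                        "beta_adj": res.beta_adj, "p_adj": res.p_adj,
                        "or_unadj": res.or_unadj if res.beta_unadj == res.beta_unadj else float("nan"),
                        "or_adj": res.or_adj if res.beta_adj == res.beta_adj else float("nan"),
                        "delta_or_fraction": res.delta_or_fraction,
                        "confounded": res.confounded,
                        "monomorphic": res.monomorphic,
                        "significant_adj": res.significant_adj,
                    }
                )
            results[(set_name, stype)] = cell
    assoc_frame = pd.DataFrame(assoc_rows)
    assoc_frame.to_csv(out / "association.tsv", sep="\t", index=False)
    manhattan = assoc_frame.query("set == 'training' and sample_type == 'blood'")[
        ["chrom", "pos", "p_adj"]
    ].copy()
    manhattan["neg_log10_p"] = -np.log10(manhattan["p_adj"])
    manhattan.to_csv(out / "manhattan.tsv", sep="\t", index=False)
    counts["variants_tested"] = int(sim.n_variants)

    # --- triage -----------------------------------------------------------
    confirmed, adjusted_only = confirm_variants(results, thresh.threshold)
    gm_blood = merged_by_type["blood"]
    gm_tumor = merged_by_type["tumor"]
    is_case = (gm_blood.samples["cohort"] == "case").to_numpy()
    is_ctrl = ~is_case
    train_mask = gm_blood.samples.index.isin(sets["training"])
    rng_ext = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
    summaries = []
    for j in range(gm_blood.n_variants):
        key = tuple(gm_blood.variants.iloc[j][["chrom", "pos", "ref", "alt"]])
        maf_blood = allele_frequency(gm_blood.genotypes[is_case, j])
        maf_tumor = allele_frequency(gm_tumor.genotypes[is_case, j])
        maf_ctrl = allele_frequency(gm_blood.genotypes[is_ctrl, j])
        # external reference behaves like an independent database: close to
        # the internal control frequency for ordinary variants, but blind
        # to variants absent from reference cohorts (planted rare set)
        if j in sim.rare_variants:
            ext = 0.0
        else:
            ext = float(np.clip(maf_ctrl + rng_ext.normal(0, 0.01), 0, 1))
        summaries.append(
            VariantSummary(
                variant=key,
                maf_case_blood=maf_blood,
                maf_case_tumor=maf_tumor,
                maf_case_train=allele_frequency(
                    gm_blood.genotypes[is_case & train_mask, j]
                ),
                maf_case_valid=allele_frequency(
                    gm_blood.genotypes[is_case & ~train_mask, j]
                ),
                maf_control_internal=maf_ctrl,
                maf_external=ext,
                tri_allelic=bool(gm_blood.variants.iloc[j]["multiallelic_split"]),
                significant={
                    cell: results[cell][key].significant_adj
                    for cell in results
                    if key in results[cell]
                },
            )
        )
    decisions = triage_variants(summaries, confirmed, adjusted_only, config.triage)
    interesting = [
        i for i, d in enumerate(decisions)
        if d.status in ("confirmed", "rare_candidate", "somatic_candidate")
    ]
    clusters = linkage_clusters(
        gm_blood.genotypes[:, interesting],
        [decisions[i].variant for i in interesting],
        config.triage.ld_r2,
    )
    for d in decisions:
        d.linkage_cluster = clusters.get(d.variant)
    triage_table = write_triage_table(decisions, summaries, out / "triage.tsv")
    rare_table = triage_table[
        triage_table["rare_class"].isin(["rare", "rare_enriched"])
    ].reset_index(drop=True)
    rare_table.to_csv(out / "rare_variants.tsv", sep="\t", index=False)
    counts["variants_confirmed"] = sum(
        d.status == "confirmed" for d in decisions
    )
    for code, ascii_name in ASCII_CODES.items():
        counts[f"excluded_{ascii_name}"] = sum(
            code in d.exclusion_codes for d in decisions
        )
    counts["rare_candidates"] = int(
        (triage_table["rare_class"].isin(["rare", "rare_enriched"])).sum()
    )
    counts["somatic_candidates"] = int(triage_table["somatic"].sum())
    # conservation check: every variant is accounted for exactly once
    n_excluded = sum(d.status == "excluded" for d in decisions)
    n_other = sum(
        d.status in ("rare_candidate", "somatic_candidate", "not_confirmed")
        for d in decisions
    )
    assert counts["variants_confirmed"] + n_excluded + n_other == len(decisions)

    # --- poly(A) ----------------------------------------------------------
    polya_rows = []
    alu_by_name = {a.element.chrom: a for a in alus}
    for rec in polya_truth:
        alu = alu_by_name[rec["sequence"]]
        res = polya_extension(
            sequences[rec["sequence"]], alu, rec["pos"], rec["ref"], rec["alt"]
        )
        polya_rows.append(
            {
                "sequence": rec["sequence"],
                "pos": rec["pos"],
                "ref": rec["ref"],
                "alt": rec["alt"],
                "region": res.region,
                "run_before": res.run_before,
                "run_after": res.run_after,
                "extension": res.extension,
            }
        )
    polya_table = pd.DataFrame(polya_rows)
    polya_table.to_csv(out / "polya.tsv", sep="\t", index=False)
    counts["polya_variants"] = len(polya_table)

    # --- manifest ---------------------------------------------------------
    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(
        json.dumps({"files": manifest, "counts": counts}, indent=2, sort_keys=True)
    )
    for stage, value in counts.items():
        log.info("%s: %s", stage, value)
    return PipelineResult(
        manifest=manifest,
        counts=counts,
        triage_table=triage_table,
        rare_table=rare_table,
        polya_table=polya_table,
    )


def write_triage_table(
    decisions, summaries, path: str | Path | None = None
) -> pd.DataFrame:
    """One row per variant with frequencies, status and exclusion codes.

    Exclusion codes are written twice: once with the conventional
    dagger/double-dagger/lozenge symbols and once as ASCII aliases for
    toolchain safety. Rows are ordered by (chrom, pos, alt).
    """
    by_key = {s.variant: s for s in summaries}
    rows = []
    for d in decisions:
        s = by_key[d.variant]
        rows.append(
            {
                "chrom": d.variant[0],
                "pos": d.variant[1],
                "ref": d.variant[2] if len(d.variant) > 3 else "",
                "alt": d.variant[-1],
                "gene": s.gene,
                "maf_case_blood": s.maf_case_blood,
                "maf_case_tumor": s.maf_case_tumor,
                "maf_control_internal": s.maf_control_internal,
                "maf_external": s.maf_external,
                "status": d.status,
                "codes": d.symbols,
                "codes_ascii": ",".join(
                    sorted(ASCII_CODES[c] for c in d.exclusion_codes)
                ),
                "adjusted_only": d.adjusted_only,
                "inconclusive_db": d.inconclusive_db,
                "rare_class": d.rare_class,
                "somatic": d.somatic,
                "linkage_cluster": d.linkage_cluster,
            }
        )
    table = pd.DataFrame(rows).sort_values(["chrom", "pos", "alt"]).reset_index(
        drop=True
    )
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
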