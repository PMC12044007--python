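"""Configuration-driven orchestration of the locus-characterization stages.

A :class:`PipelineConfig` (round-trippable through YAML) names the input
files and thresholds for each stage; :func:`run_pipeline` executes the
enabled stages in dependency order, assembles a :class:`LocusReport`, and
writes it as JSON plus per-stage TSVs.  Stage failures are recorded in the
report and skip downstream dependents rather than aborting the run.  All
randomness derives from the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc_meta, coloc_abf, fine_mapping, io as lio
from . import allelic_motif as motif
from . import assay_quant, insilico_knockdown, substrate_triage, synthetic_data


@dataclass
class PipelineConfig:
    """Stage toggles, file paths, and thresholds with their printed defaults."""

    seed: int = 0
    out_dir: str = "locus_report"

    # stage toggles
    run_simulate: bool = True
    run_meta: bool = True
    run_finemap: bool = True
    run_motif: bool = False
    run_coloc: bool = True
    run_substrates: bool = True
    run_knockdown: bool = True
    run_assays: bool = True

    # file paths (empty string = use synthetic inputs from run_simulate)
    studies_path: str = ""
    summary_path: str = ""
    dosages_path: str = ""
    pfm_path: str = ""
    fasta_path: str = ""
    snp_table_path: str = ""
    counts_path: str = ""
    gmt_path: str = ""

    # thresholds (defaults are the conventional printed values)
    llr_max: float = 100.0
    r2_min: float = 0.8
    coverage: float = 0.9
    L: int = 10
    fold_min: float = 1.0
    fc_min: float = 1.5
    p_max: float = 0.05
    fdr_max: float = 0.05
    log2fc_min: float | None = 0.5
    n_perm: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.coverage < 1):
            raise ValueError("coverage must be in (0, 1)")
        if self.llr_max <= 0 or self.fc_min <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 <= self.r2_min <= 1):
            raise ValueError("r2_min must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class LocusReport:
    config: dict
    provenance: dict
    stages: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "provenance": self.provenance,
                "stages": self.stages,
                "failures": self.failures,
            },
            indent=2,
            sort_keys=True,
            default=_jsonify,
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> LocusReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = LocusReport(
        config=config.to_dict(),
        provenance={
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
    )

    sim = None
    if config.run_simulate:
        try:
            sim = _stage_simulate(config, out, report)
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            report.failures["simulate"] = str(exc)

    for name, fn in [
        ("meta", _stage_meta),
        ("finemap", _stage_finemap),
        ("motif", _stage_motif),
        ("coloc", _stage_coloc),
        ("substrates", _stage_substrates),
        ("knockdown", _stage_knockdown),
        ("assays", _stage_assays),
    ]:
        if not getattr(config, f"run_{name}"):
            continue
        try:
            fn(config, sim, out, report)
        except Exception as exc:  # noqa: BLE001
            report.failures[name] = str(exc)

    (out / "locus_report.json").write_text(report.to_json())
    return report


def _stage_simulate(config, out, report):
    sc = synthetic_data.SimConfig(seed=config.seed)
    dosages, ld = synthetic_data.simulate_ld_genotypes(sc)
    summary = synthetic_data.simulate_case_control_summary(dosages, sc)
    t1, t2 = synthetic_data.simulate_two_trait_summaries(dosages, True, sc)
    psm, cmap, dose, psm_truth = synthetic_data.simulate_psm_experiment(
        seed=config.seed
    )
    counts, rna_truth = synthetic_data.simulate_rnaseq(
        n_genes=400, n_samples=120, planted_sets={"SET_UP": 25}, seed=config.seed
    )
    qpcr, q_truth = synthetic_data.simulate_qpcr(
        ["chip_site"], {"chip_site": 0.95}, seed=config.seed
    )
    dosages.to_csv(out / "dosages.tsv", sep="\t", index=False)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    counts.to_csv(out / "counts.tsv", sep="\t")
    truth = {
        "causal_variants": [dosages.columns[sc.causal_index]],
        "substrate_proteins": sorted(psm_truth.substrate_proteins),
        "enriched_gene_sets": sorted(rna_truth.enriched_gene_sets),
        "qpcr_efficiency": q_truth.qpcr_efficiency,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    report.stages["simulate"] = {
        "n_individuals": sc.n_individuals,
        "n_variants": sc.n_variants,
        "truth": truth,
    }
    return {
        "sim_config": sc,
        "dosages": dosages,
        "ld": ld,
        "summary": summary,
        "trait1": t1,
        "trait2": t2,
        "psm": psm,
        "condition_map": cmap,
        "dose": dose,
        "psm_truth": psm_truth,
        "counts": counts,
        "rna_truth": rna_truth,
        "qpcr": qpcr,
        "qpcr_truth": q_truth,
    }


def _stage_meta(config, sim, out, report):
    if config.studies_path:
        studies = pd.read_csv(config.studies_path, sep="\t")
    else:
        raise ValueError("meta stage needs studies_path (TSV of study rows)")
    res = assoc_meta.meta_from_table(studies)
    report.stages["meta"] = {
        "n_studies": len(studies),
        "or": res.or_point,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p": res.p,
    }


def _stage_finemap(config, sim, out, report):
    if config.summary_path:
        summary = lio.read_summary_stats(config.summary_path)
        dosages = lio.read_dosages(config.dosages_path)
    elif sim is not None:
        summary, dosages = sim["summary"], sim["dosages"]
    else:
        raise ValueError("finemap stage needs summary/dosages or simulate")
    tag = summary.loc[summary["p"].idxmin(), "variant_id"]
    llr = fine_mapping.llr_from_pvalues(summary, tag)
    r2 = fine_mapping.ld_r2(dosages, tag)
    table = summary.assign(
        llr=llr.loc[summary["variant_id"]].to_numpy(),
        r2=r2.loc[summary["variant_id"]].to_numpy(),
    )
    candidates = fine_mapping.llr_ld_filter(
        table, tag, llr_max=config.llr_max, r2_min=config.r2_min
    )
    susie_summary = None
    if sim is not None:
        # refit on the simulated case-control phenotype (regenerated from
        # the same stream) for a credible-set view
        sc = sim["sim_config"]
        fit = fine_mapping.susie_fit(
            dosages,
            _working_phenotype(dosages, sc),
            L=config.L,
            coverage=config.coverage,
        )
        susie_summary = {
            "n_credible_sets": len(fit.credible_sets),
            "sets": [cs.members for cs in fit.credible_sets],
            "max_pip_variant": fit.pip.idxmax(),
            "purity_min": fit.purity_min,
        }
        table = table.assign(pip=fit.pip.loc[table["variant_id"]].to_numpy())
    table.to_csv(out / "finemap.tsv", sep="\t", index=False)
    report.stages["finemap"] = {
        "tag": tag,
        "n_input": len(table),
        "n_candidates": len(candidates),
        "candidates": candidates,
        "susie": susie_summary,
    }


def _working_phenotype(dosages, sc):
    rng = np.random.default_rng(sc.seed + _ph_offset())
    g = dosages.to_numpy(dtype=float)[:, sc.causal_index]
    gz = (g - g.mean()) / (g.std() or 1.0)
    eta = sc.causal_beta * gz
    alpha = synthetic_data._solve_intercept(eta, sc.case_fraction)
    return (
        rng.uniform(size=len(gz)) < 1.0 / (1.0 + np.exp(-(alpha + eta)))
    ).astype(float)


def _ph_offset():
    return synthetic_data._STREAM_OFFSETS["phenotype"]


def _stage_motif(config, sim, out, report):
    pfms = lio.read_jaspar_pfms(config.pfm_path)
    seqs = lio.read_fasta(config.fasta_path)
    snps = lio.read_snp_table(config.snp_table_path)
    reports = []
    for _, row in snps.iterrows():
        seq = seqs[row["sequence_id"]]
        for name, counts in pfms.items():
            pwm = motif.pfm_to_pwm(counts, name=name)
            reports.append(
                motif.snp_motif_report(
                    pwm,
                    seq,
                    int(row["position"]),
                    row["allele1"],
                    row["allele2"],
                    snp_id=row["snp_id"],
                )
            )
    ranked = motif.rank_disrupted_motifs(reports, fold_min=config.fold_min)
    pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "motif": r.motif,
                "p_allele1": r.p_allele1,
                "p_allele2": r.p_allele2,
                "fold_change": r.fold_change,
                "stronger_allele": r.stronger_allele,
            }
            for r in ranked
        ]
    ).to_csv(out / "motif_reports.tsv", sep="\t", index=False)
    report.stages["motif"] = {
        "n_reports": len(reports),
        "n_past_fold_min": len(ranked),
        "top": ranked[0].motif if ranked else None,
    }


def _stage_coloc(config, sim, out, report):
    if sim is None:
        raise ValueError("coloc stage needs simulated two-trait summaries")
    res = coloc_abf.coloc_posteriors(sim["trait1"], sim["trait2"])
    report.stages["coloc"] = {**res.pp, "n_variants": res.n_variants}


def _stage_substrates(config, sim, out, report):
    if sim is None:
        raise ValueError("substrates stage needs simulated PSM tables")
    pilot = sorted(sim["psm_truth"].substrate_proteins)
    calls = substrate_triage.triage(
        sim["psm"],
        sim["condition_map"],
        pilot,
        sim["dose"],
        fc_min=config.fc_min,
        p_max=config.p_max,
    )
    n_enriched = sum(c.passed_enrichment for c in calls)
    n_overlap = sum(c.in_pilot_overlap for c in calls)
    finals = [c.protein_id for c in calls if c.final_candidate]
    report.stages["substrates"] = {
        "n_proteins": len(calls),
        "n_enriched": n_enriched,
        "n_pilot_overlap": n_overlap,
        "n_final": len(finals),
        "final_candidates": finals,
    }


def _stage_knockdown(config, sim, out, report):
    if config.counts_path:
        counts = lio.read_counts(config.counts_path)
        driver = counts.index[0]
        gene_sets = lio.read_gmt(config.gmt_path) if config.gmt_path else None
    elif sim is not None:
        counts = sim["counts"]
        driver = "DRIVER"
        gene_sets = getattr(sim["rna_truth"], "gene_sets", None)
    else:
        raise ValueError("knockdown stage needs counts or simulate")
    de, gsea, selected = insilico_knockdown.insilico_knockdown(
        counts,
        driver,
        gene_sets=gene_sets,
        fdr_max=config.fdr_max,
        log2fc_min=config.log2fc_min,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    de.table.to_csv(out / "de_results.tsv", sep="\t")
    report.stages["knockdown"] = {
        "n_genes_tested": len(de.table),
        "dispersion": de.dispersion,
        "n_selected": len(selected),
        "quartile_n": len(de.groups[0]),
        "gsea_sets": (
            gsea.table[["es", "nes", "p_perm", "fdr"]].to_dict("index")
            if gsea is not None and len(gsea.table)
            else {}
        ),
    }


def _stage_assays(config, sim, out, report):
    if sim is None:
        raise ValueError("assays stage needs simulated qPCR data")
    qpcr = sim["qpcr"]
    truth = sim["qpcr_truth"].qpcr_efficiency
    curves = {}
    for target, sub in qpcr.groupby("target"):
        curve = assay_quant.fit_standard_curve(sub["quantity"], sub["ct"])
        curves[target] = {
            "slope": curve.slope,
            "efficiency": curve.efficiency,
            "true_efficiency": truth.get(target),
            "r_squared": curve.r_squared,
        }
    report.stages["assays"] = {"standard_curves": curves}
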