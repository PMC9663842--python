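"""End-to-end orchestration from a single YAML-style config.

Stage order mirrors the study design: phenotype comparison -> differential
expression (DEGs and |log2FC|>1 candidates) -> per-sex co-expression
networks and DcoExp calling -> DML/DMR calling and annotation -> multiblock
sPLS-DA integration (build, fit, select, pair, refit, evaluate) ->
module-trait correlation restricted to DcoExp modules harbouring selected
genes -> QTL/term enrichment.  Every stage writes its declared TSV/JSON
outputs; a manifest records the seed and a parameter hash so identical
configs reproduce identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression as coex
from . import enrichment as enr
from . import expression as expr
from . import integration as integ
from . import io as pio
from . import methylation as meth
from . import phenostats as pheno
from .simulate import SimulationConfig, simulate_experiment

log = logging.getLogger("perifat")

DEFAULT_PARAMS = dict(
    fpkm_threshold=0.2,
    deg_fdr_max=0.05,
    deg_lfc_min=2.0,
    candidate_lfc_min=1.0,
    min_module_size=30,
    min_module_cor=0.5,
    kmeans_iterations=20,
    dcoexp_fdr_max=0.05,
    smoothing_window_bp=500,
    dml_p_max=0.001,
    dmr_p_site=0.01,
    dmr_min_len=50,
    dmr_min_sites=3,
    dmr_min_pct_sig=0.5,
    dmr_cluster_gap=100,
    dmr_merge_gap=50,
    promoter_up=1000,
    promoter_down=1000,
    ncomp=2,
    design=1.0,
    trait_p_max=0.05,
    enrichment_fdr_max=0.05,
    term_group_k=5,
)


class PipelineConfig:
    """Input paths (or a ``simulate`` block), stage parameters, outdir, seed."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.outdir = Path(raw.get("outdir", "perifat_out"))
        self.seed = int(raw.get("seed", 0))
        self.params = dict(DEFAULT_PARAMS)
        self.params.update(raw.get("params", {}))
        self.simulate = raw.get("simulate")
        self.inputs = raw.get("inputs", {})
        if self.simulate is None:
            needed = ["counts", "calls", "gff", "qtl", "metadata"]
            missing = [k for k in needed if k not in self.inputs]
            if missing:
                raise ValueError(f"config missing inputs {missing} and no simulate block")
            for k in needed:
                if not Path(self.inputs[k]).exists():
                    raise FileNotFoundError(self.inputs[k])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def param_hash(self) -> str:
        blob = json.dumps(
            dict(params=self.params, seed=self.seed, simulate=self.simulate,
                 inputs={k: str(v) for k, v in self.inputs.items()}),
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        for tup_key in ("de_log2fc_range", "dmr_length_range", "dmr_delta_range",
                        "nb_dispersion_range", "bb_dispersion_range",
                        "dmr_site_spacing"):
            if tup_key in sim_kwargs:
                sim_kwargs[tup_key] = tuple(sim_kwargs[tup_key])
        if "module_spec" in sim_kwargs:
            sim_kwargs["module_spec"] = [
                (int(s), float(r), x) for s, r, x in sim_kwargs["module_spec"]
            ]
        if "trait_spec" in sim_kwargs:
            sim_kwargs["trait_spec"] = {
                k: (int(v[0]), float(v[1])) for k, v in sim_kwargs["trait_spec"].items()
            }
        sim = SimulationConfig(**sim_kwargs)
        counts, calls, genes, qtls, metadata, truth = simulate_experiment(sim)
        return counts, calls, genes, qtls, metadata, truth
    counts = pio.read_counts(config.inputs["counts"])
    calls = pio.read_methylation_calls(config.inputs["calls"])
    genes = pio.read_gene_models(config.inputs["gff"])
    qtls = pio.read_qtl_table(config.inputs["qtl"])
    metadata = pio.read_metadata(config.inputs["metadata"])
    return counts, calls, genes, qtls, metadata, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result bundle of in-memory objects."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    p = config.params
    bundle: dict = {}
    try:
        counts, calls, genes, qtls, metadata, truth = _load_inputs(config)
        bundle.update(counts=counts, calls=calls, genes=genes, qtls=qtls,
                      metadata=metadata, truth=truth)
        if truth is not None:
            pio.write_counts(counts, out / "counts.tsv")
            pio.write_methylation_calls(calls, out / "methylation_calls.tsv")
            pio.write_gene_models(genes, out / "genes.gff3")
            pio.write_qtl_table(qtls, out / "qtl_db.tsv")
            pio.write_metadata(metadata, out / "metadata.tsv")
            truth.to_json(out / "truth.json")

        # --- phenotype statistics
        log.info("stage: phenostats")
        trait_cmp = pheno.compare_traits(metadata, p_max=p["trait_p_max"])
        pheno.comparisons_to_frame(trait_cmp).to_csv(
            out / "trait_comparison.tsv", sep="\t", index=False
        )
        bundle["trait_comparison"] = trait_cmp

        # --- differential expression
        log.info("stage: expression")
        fpkm_mat = expr.fpkm(counts)
        kept = expr.filter_low_expression(fpkm_mat, metadata.sexes, p["fpkm_threshold"])
        sub_counts = pio.ExpressionCountMatrix(
            counts.counts.loc[kept, metadata.samples], counts.gene_length_bp.loc[kept]
        )
        de_model = expr.SexDifferentialExpression(sub_counts, metadata.sexes)
        de_res = de_model.fit()
        de_res.to_tsv(out / "de_results.tsv")
        degs = de_res.call_degs(p["deg_fdr_max"], p["deg_lfc_min"])
        candidates = de_res.call_candidates(p["candidate_lfc_min"])
        bundle.update(fpkm=fpkm_mat, de_results=de_res, degs=degs, candidates=candidates)

        # --- per-sex co-expression and DcoExp
        log.info("stage: coexpression")
        module_sets = {}
        for sex in ("M", "F"):
            samples = metadata.samples_of_sex(sex)
            ms = coex.build_network(
                fpkm_mat.loc[kept, samples],
                sex=sex,
                min_module_size=p["min_module_size"],
                min_module_cor=p["min_module_cor"],
                kmeans_iterations=p["kmeans_iterations"],
            )
            ms.to_frame().to_csv(out / f"modules_{sex}.tsv", sep="\t", index=False)
            module_sets[sex] = ms
        background = sorted(
            set(module_sets["M"].assignment.index) | set(module_sets["F"].assignment.index)
        )
        dcoexp = coex.dcoexp_fisher(
            module_sets["M"], module_sets["F"], background, p["dcoexp_fdr_max"]
        )
        pd.DataFrame([d.__dict__ for d in dcoexp]).to_csv(
            out / "dcoexp.tsv", sep="\t", index=False
        )
        bundle.update(module_sets=module_sets, dcoexp=dcoexp)

        # --- methylation
        log.info("stage: methylation")
        dml_model = meth.DifferentialMethylation(
            calls, metadata.sexes, window_bp=p["smoothing_window_bp"]
        )
        dml_res = dml_model.fit()
        dml_res.table.to_csv(out / "dml.tsv", sep="\t", index=False)
        dmrs = dml_res.call_dmrs(
            p_site=p["dmr_p_site"],
            min_len=p["dmr_min_len"],
            min_sites=p["dmr_min_sites"],
            min_pct_sig=p["dmr_min_pct_sig"],
            cluster_gap=p["dmr_cluster_gap"],
            merge_gap=p["dmr_merge_gap"],
        )
        dmrs = [
            meth.annotate_genomic_context(d, genes, p["promoter_up"], p["promoter_down"])
            for d in dmrs
        ]
        meth.dmrs_to_frame(dmrs).to_csv(out / "dmr_annotated.tsv", sep="\t", index=False)
        ctx_summary = meth.context_summary(calls, metadata.sexes)
        pd.DataFrame([c.__dict__ for c in ctx_summary]).to_csv(
            out / "context_summary.tsv", sep="\t", index=False
        )
        bundle.update(dml_results=dml_res, dmrs=dmrs, context_summary=ctx_summary)

        # --- integration
        log.info("stage: integration")
        dmr_ids = [
            f"{d.interval.chrom}:{d.interval.start}-{d.interval.end}:{d.context}"
            for d in dmrs
        ]
        if candidates and dmrs:
            dmr_feat = pd.DataFrame(
                {s: np.nan for s in metadata.samples}, index=dmr_ids
            )
            for did, d in zip(dmr_ids, dmrs):
                dmr_feat.loc[did] = meth.dmr_mean_methylation(calls, d)
            blocks = integ.build_blocks(fpkm_mat, candidates, dmr_feat, metadata.sexes)
            fit = integ.BlockSPLSDA(
                blocks, ncomp=p["ncomp"], design=p["design"]
            ).fit()
            selected = fit.select_variables()
            annotations = dict(zip(dmr_ids, dmrs))
            paired_genes, paired_dmrs = integ.pair_dmrs_to_genes(
                selected.get("mrna", []), selected.get("meth", []), annotations
            )
            evaluation = fit.evaluate()
            refit = refit_eval = None
            if paired_genes and paired_dmrs:
                refit, refit_eval = integ.overlap_refit(
                    blocks, paired_genes, paired_dmrs,
                    ncomp=p["ncomp"], design=p["design"],
                )
            pd.Series(selected.get("mrna", []), name="gene_id").to_csv(
                out / "selected_genes.tsv", sep="\t", index=False
            )
            pd.Series(selected.get("meth", []), name="dmr_id").to_csv(
                out / "selected_dmrs.tsv", sep="\t", index=False
            )
            with open(out / "evaluation.json", "w", encoding="utf-8") as fh:
                json.dump(
                    dict(
                        initial=evaluation.to_dict(),
                        refit=refit_eval.to_dict() if refit_eval else None,
                        n_paired_genes=len(paired_genes),
                        n_paired_dmrs=len(paired_dmrs),
                    ),
                    fh,
                    indent=1,
                )
            bundle.update(
                blocks=blocks, splsda=fit, selected=selected,
                paired_genes=paired_genes, paired_dmrs=paired_dmrs,
                refit=refit, evaluation=evaluation, refit_evaluation=refit_eval,
            )
            selected_genes = paired_genes if paired_genes else selected.get("mrna", [])
        else:
            log.info("integration skipped: no candidates or no DMRs")
            selected_genes = []

        # --- candidate DcoExp modules: harbour selected genes + trait link
        log.info("stage: module-trait")
        mt_rows = []
        candidate_modules = []
        for sex, ms in module_sets.items():
            specific = {d.module for d in dcoexp if d.sex == sex and d.specific}
            corr = coex.module_trait_correlation(ms, metadata, p_max=p["trait_p_max"])
            for c in corr:
                c_dict = c.__dict__
                c_dict["dcoexp"] = c.module in specific
                harbours = bool(set(ms.members(c.module)) & set(selected_genes))
                c_dict["harbours_selected_gene"] = harbours
                c_dict["candidate"] = bool(
                    c_dict["dcoexp"] and harbours and c.significant
                )
                mt_rows.append(c_dict)
                if c_dict["candidate"]:
                    candidate_modules.append((sex, c.module, c.trait))
        pd.DataFrame(mt_rows).to_csv(
            out / "module_trait_correlation.tsv", sep="\t", index=False
        )
        bundle["candidate_modules"] = candidate_modules

        # --- enrichment
        log.info("stage: enrichment")
        if selected_genes:
            gene_index = {g.gene_id: g for g in genes}
            sel_models = [gene_index[g] for g in selected_genes if g in gene_index]
            annotated = enr.annotate_qtl_overlap(sel_models, qtls)
            if any(annotated.values()):
                qtl_res, type_share = enr.qtl_enrichment(annotated, qtls)
                enr.enrichment_to_frame(qtl_res).to_csv(
                    out / "qtl_enrichment.tsv", sep="\t", index=False
                )
                type_share.rename("percent").to_csv(out / "qtl_type_share.tsv", sep="\t")
                bundle.update(qtl_enrichment=qtl_res, qtl_type_share=type_share)

        manifest = dict(
            seed=config.seed,
            param_hash=config.param_hash(),
            n_genes=len(counts.genes),
            n_sites=len(calls.table),
            n_degs=len(degs),
            n_candidates=len(candidates),
            n_dmrs=len(dmrs),
            n_candidate_modules=len(candidate_modules),
        )
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        bundle["manifest"] = manifest
        return bundle
    except Exception:
        log.exception("pipeline halted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
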