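"""End-to-end orchestration: QC -> marginal filter -> per-cohort interaction
scan -> meta-analysis -> cis-eQTL/SMR -> heritability -> pathway enrichment.

Each stage writes one TSV into the output directory and appends its record
count to a run log, so a rerun with the same seed reproduces every file.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import eqtl as eqtl_mod
from . import interaction, meta, pathways, qc
from .heritability import estimate_h2
from .io import write_gmt, write_plink
from .simulate import SimulationConfig, simulate_annotation, simulate_cohort, simulate_expression
from .types import GenotypeDataset, PipelineConfig, records_to_frame


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    sim: Optional[SimulationConfig] = None,
    cohort_data: Optional[Dict[str, GenotypeDataset]] = None,
) -> Dict[str, object]:
    """Run every stage and write one TSV per stage plus ``run_log.json``.

    Either supply per-cohort datasets in ``cohort_data`` or a
    :class:`SimulationConfig` whose seed is taken from the pipeline config.
    Returns the in-memory stage outputs keyed by stage name.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log: Dict[str, object] = {"seed": config.seed, "thresholds": {
        "marginal_alpha": config.marginal_alpha,
        "gw_alpha": config.gw_alpha,
        "maf_min": config.maf_min,
        "callrate_min": config.callrate_min,
        "hwe_alpha": config.hwe_alpha,
        "ibs_max": config.ibs_max,
        "cis_window": config.cis_window,
        "family_alpha": config.family_alpha,
        "flank": config.flank,
        "lifetime_risk": config.lifetime_risk,
    }, "counts": {}}
    out: Dict[str, object] = {}

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise StageError(name, exc) from exc
        return deco

    # --- inputs -----------------------------------------------------------
    if cohort_data is None:
        if sim is None:
            sim = SimulationConfig(seed=config.seed)
        else:
            sim = replace(sim, seed=config.seed)
        cohort_data = {
            label: simulate_cohort(sim, label) for label in config.cohorts
        }
        for label, ds in cohort_data.items():
            write_plink(ds, os.path.join(config.out_dir, f"sim_{label}"))

    # --- QC ---------------------------------------------------------------
    def do_qc():
        cleaned = {}
        frames = []
        for label, ds in cohort_data.items():
            ds1, rep_s = qc.apply_sample_filters(ds, config.callrate_min, config.ibs_max)
            ds2, rep_v = qc.apply_snp_filters(ds1, config.maf_min, config.callrate_min, config.hwe_alpha)
            cleaned[label] = ds2
            f = pd.concat([rep_s.to_frame(), rep_v.to_frame()])
            f.insert(0, "cohort", label)
            frames.append(f)
        report = pd.concat(frames, ignore_index=True)
        report.to_csv(os.path.join(config.out_dir, "qc_report.tsv"), sep="\t", index=False)
        log["counts"]["qc_removed"] = len(report)
        return cleaned
    cleaned = _stage("qc")(do_qc)

    # --- per-cohort interaction scans ------------------------------------
    def do_scan():
        scans = {}
        for label, ds in cleaned.items():
            res = interaction.pairwise_scan(ds, config.marginal_alpha)
            scans[label] = res
            frame = records_to_frame(res) if res else pd.DataFrame(
                columns=[f.name for f in dataclasses.fields(interaction.PairResult)])
            frame.to_csv(os.path.join(config.out_dir, f"scan_{label}.tsv"), sep="\t", index=False)
            log["counts"][f"scan_{label}"] = len(res)
        return scans
    scans = _stage("scan")(do_scan)

    # --- meta-analysis ----------------------------------------------------
    def do_meta():
        labels = list(cleaned)
        res = meta.meta_scan(scans[labels[0]], scans[labels[1]], config.gw_alpha) \
            if len(labels) >= 2 else []
        frame = records_to_frame(res) if res else pd.DataFrame()
        frame.to_csv(os.path.join(config.out_dir, "meta.tsv"), sep="\t", index=False)
        log["counts"]["meta_pairs"] = len(res)
        log["counts"]["meta_significant"] = int(sum(r.significant for r in res))
        return res
    meta_res = _stage("meta")(do_meta)

    # --- cis-eQTL + SMR on the first cohort ------------------------------
    def do_eqtl():
        label = list(cleaned)[0]
        ds = cleaned[label]
        if sim is None:
            return [], []
        base = cohort_data[label]  # planted (snp, probe) pairs index pre-QC columns
        expr = simulate_expression(base, sim)
        expr = eqtl_mod.filter_expression_probes(expr)
        # candidate SNPs: members of meta pairs, else strongest marginal SNPs
        cand = sorted({s for r in meta_res for s in (r.snp1_id, r.snp2_id)})
        if not cand:
            pm = interaction.marginal_trend_pvalues(base)
            cand = list(base.snps["snp_id"].iloc[np.argsort(pm)[:5]])
        snp_idx = {sid: k for k, sid in enumerate(base.snps["snp_id"])}
        eqtl_records, smr_records = [], []
        for sid in cand:
            v = snp_idx[sid]
            spos = int(base.snps["pos"].iloc[v])
            schrom = str(base.snps["chrom"].iloc[v])
            for p in range(expr.n_probes):
                prow = expr.probes.iloc[p]
                if str(prow["chrom"]) != schrom or abs(int(prow["pos"]) - spos) > config.cis_window:
                    continue
                rec = eqtl_mod.cis_eqtl_huber(expr, base, v, p, config.cis_window)
                if rec is None:
                    continue
                eqtl_records.append(rec)
                bzy, sezy, _ = eqtl_mod.gwas_log_odds(base, v)
                smr_records.append(
                    eqtl_mod.smr_test(bzy, sezy, rec.beta_zx, rec.se_zx, rec.snp_id, rec.probe_id)
                )
        alpha = eqtl_mod.holm_sidak_alpha(max(len(eqtl_records), 1), config.family_alpha)
        log["counts"]["eqtl_tested"] = len(eqtl_records)
        log["eqtl_sidak_alpha"] = alpha
        ef = records_to_frame(eqtl_records) if eqtl_records else pd.DataFrame()
        ef.to_csv(os.path.join(config.out_dir, "eqtl.tsv"), sep="\t", index=False)
        sf = records_to_frame(smr_records) if smr_records else pd.DataFrame()
        sf.to_csv(os.path.join(config.out_dir, "smr.tsv"), sep="\t", index=False)
        return eqtl_records, smr_records
    eqtl_records, smr_records = _stage("eqtl")(do_eqtl)

    # --- heritability of the identified loci ------------------------------
    def do_h2():
        label = list(cleaned)[0]
        ds = cleaned[label]
        loci = sorted({s for r in meta_res for s in (r.snp1_id, r.snp2_id)})
        snp_idx = {sid: k for k, sid in enumerate(ds.snps["snp_id"])}
        subset = [snp_idx[s] for s in loci if s in snp_idx]
        if len(subset) < 1:
            subset = None
        est = estimate_h2(ds, subset, K=config.lifetime_risk)
        pd.DataFrame([est.__dict__]).to_csv(
            os.path.join(config.out_dir, "h2.tsv"), sep="\t", index=False)
        log["counts"]["h2_snps"] = est.n_snps_used
        return est
    h2_est = _stage("h2")(do_h2)

    # --- pathway enrichment ----------------------------------------------
    def do_pathway():
        gene_table, gene_sets = simulate_annotation(sim or SimulationConfig(seed=config.seed))
        write_gmt(gene_sets, os.path.join(config.out_dir, "gene_sets.gmt"))
        sources = {}
        for label, ds in cleaned.items():
            pm = interaction.marginal_trend_pvalues(ds)
            sources[label] = pd.DataFrame({
                "snp_id": ds.snps["snp_id"],
                "chrom": ds.snps["chrom"],
                "pos": ds.snps["pos"],
                "p": np.clip(pm, 1e-300, 1.0),
            })
        res = pathways.enrich(sources, gene_table, gene_sets, config.flank)
        frame = records_to_frame(res) if res else pd.DataFrame()
        frame.to_csv(os.path.join(config.out_dir, "pathway.tsv"), sep="\t", index=False)
        log["counts"]["pathways"] = len(res)
        return res
    pathway_res = _stage("pathway")(do_pathway)

    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=float)

    out.update(
        cohorts=cleaned, scans=scans, meta=meta_res, eqtl=eqtl_records,
        smr=smr_records, h2=h2_est, pathways=pathway_res, log=log,
    )
    return out
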