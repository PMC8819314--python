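"""End-to-end orchestration of the cohort analysis and the ddPCR batch.

``run_cohort`` executes alteration calling -> stratification -> cohort
statistics -> expression signature (-> enrichment when gene sets are given)
and writes every intermediate to the output directory; ``run_ddpcr`` gates,
quantifies, and calls a batch of droplet CSVs and emits the patient-level
summary.  Both are deterministic under a fixed config and seed, and every
number in the run report is re-derivable from the written intermediates.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna, cohort, ddpcr, enrichment, expression, io
from .config import RunConfig

log = logging.getLogger("mesokit")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _round_floats(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return None if math.isnan(obj) else round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_cohort(config: RunConfig) -> dict:
    """Run the full cohort analysis; returns the run report dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"seed": config.seed}}

    stage = "inputs"
    try:
        profiles = io.read_seg(config.segments)
        mutations = io.read_maf(config.mutations)
        expr = io.read_expression(config.expression) if config.expression else None
        clinical = io.read_clinical(config.clinical) if config.clinical else None
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e
    log.info("inputs: %d profiles, %d mutation records", len(profiles), len(mutations))

    stage = "cna_alteration"
    try:
        thresholds = config.cna_thresholds()
        log.info(
            "thresholds: low %+g/%+g high %+g/%+g",
            thresholds.low_gain,
            thresholds.low_loss,
            thresholds.high_gain,
            thresholds.deep_loss,
        )
        calls = cna.call_gene_alterations(
            mutations, profiles, thresholds=thresholds
        )
        strata = cna.stratify_patients(calls)
        calls_out = calls.copy()
        calls_out["evidence"] = calls_out["evidence"].map(
            lambda ev: ";".join(f"{s}={_round_floats(v)}" for s, v in ev)
        )
        calls_out.to_csv(out / "alteration_calls.tsv", sep="\t", index=False)
        strata.to_csv(out / "strata.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e
    stratum_counts = strata["stratum"].value_counts().to_dict()
    report["stratum_counts"] = {
        s.value: int(stratum_counts.get(s.value, 0)) for s in cna.Stratum
    }

    stage = "cohort_stats"
    try:
        groups = strata.set_index("patient_id")["stratum"]
        spectrum = cohort.substitution_spectrum(mutations, groups)
        spectrum.counts.to_csv(out / "substitution_spectrum.tsv", sep="\t")
        wide = calls.pivot(index="sample_id", columns="gene", values="altered")
        co = cohort.cooccurrence_test(
            wide["KRAS"].astype(bool), wide["TP53"].astype(bool)
        )
        inst = pd.DataFrame(
            [
                cohort.instability_indices(p, config.instability_threshold).__dict__
                for p in profiles.values()
            ]
        )
        # labeled as reconstructed definitions, not the source cohort's
        inst.insert(1, "definition", "reconstructed:|z|>threshold,length-weighted")
        inst.to_csv(out / "instability_indices.tsv", sep="\t", index=False)
        report["cooccurrence"] = {
            "overlap": co.overlap,
            "expected_overlap": co.expected_overlap,
            "p_enrichment": co.p_enrichment,
            "p_two_sided": co.p_two_sided,
        }
        report["mean_mutations_per_group"] = spectrum.mean_mutations_per_group.to_dict()
        surv = None
        if clinical is not None:
            rec = clinical.rename(columns={"time_days": "time"}).merge(
                strata, left_on="patient", right_on="patient_id"
            )
            rec["group"] = np.where(rec["stratum"] == "OTHER", "OTHER", "KRAS_altered")
            lr = cohort.logrank_test(rec, "group")
            hr = cohort.mantel_haenszel_hr(
                rec, "group", groups_order=["KRAS_altered", "OTHER"]
            )
            km = {
                g: cohort.km_estimate(rec[rec["group"] == g]) for g in ("KRAS_altered", "OTHER")
            }
            surv = {
                "logrank_chi2": lr.statistic,
                "logrank_p": lr.p,
                "hr_kras_vs_other": hr.hr,
                "hr_ci95": list(hr.ci95),
                "median_days": {g: km[g].median for g in km},
            }
            report["survival"] = surv
            (out / "survival.json").write_text(
                json.dumps(_round_floats(surv), indent=2)
            )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, str(e)) from e

    if expr is not None:
        stage = "expression_signature"
        try:
            sig = expression.monotone_signature(expr, strata, alpha_q=config.alpha_q)
            sig.table.to_csv(out / "signature.tsv", sep="\t")
            report["signature_size"] = len(sig.genes)
            report["signature_test"] = sig.test + " (reconstructed criterion)"
            if len(sig.genes) >= 2:
                sub = expression.zscore_rows(expr.loc[sig.genes])
                col_dend = expression.hclust_pearson_complete(sub, axis=1)
                row_dend = expression.hclust_pearson_complete(sub, axis=0)
                (out / "samples.nwk").write_text(col_dend.to_newick())
                (out / "genes.nwk").write_text(row_dend.to_newick())
                labels = col_dend.cut(2)
                labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
                altered = (
                    strata.set_index("patient_id")["stratum"] != "OTHER"
                ).reindex(labels.index)
                # enrichment in the cluster holding more altered patients
                target = (
                    pd.crosstab(labels, altered)
                    .get(True, pd.Series(0, index=[1, 2]))
                    .idxmax()
                )
                report["cluster_enrichment_p"] = expression.cluster_enrichment(
                    labels, altered, target
                )
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, str(e)) from e

    if config.gene_sets and config.ranked_list:
        stage = "enrichment"
        try:
            sets = io.read_gmt(config.gene_sets)
            ranked = io.read_ranked_list(config.ranked_list)
            rows = []
            for name, members in sets.items():
                es, p = enrichment.preranked_p(
                    ranked, members, n_perm=config.n_perm, seed=config.seed
                )
                rows.append({"name": name, "es": es, "nominal_p": p})
            pd.DataFrame(rows).to_csv(out / "gsea.tsv", sep="\t", index=False)
            report["gsea"] = _round_floats(rows)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, str(e)) from e

    report = _round_floats(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def run_ddpcr(config: RunConfig) -> pd.DataFrame:
    """Gate, quantify, and call every droplet CSV of a batch.

    Droplet files must carry a ``patient`` column (or one patient per file,
    named by the file stem).  Returns the per-patient calls table and writes
    it with a summary JSON.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    gates = config.gates()
    results: dict[str, list[ddpcr.DdpcrResult]] = {}
    for path in config.droplets:
        try:
            table = io.read_droplets(path)
        except Exception as e:  # noqa: BLE001
            raise StageError("ddpcr_inputs", f"{path}: {e}") from e
        patient_col = table["patient"] if "patient" in table.columns else Path(path).stem
        table = table.assign(patient=patient_col)
        for (patient, well, assay), grp in table.groupby(["patient", "well", "assay"]):
            if assay not in {a.value for a in ddpcr.Assay}:
                raise StageError("ddpcr_gate", f"unknown assay label {assay!r}")
            res = ddpcr.quantify_well(grp, gates, sample_id=f"{patient}:{well}")
            results.setdefault(str(patient), []).append(res)
    rows = []
    for patient in sorted(results):
        kras_alt, tp53_alt = ddpcr.call_sample(results[patient], config.tp53_range())
        rows.append(
            {
                "patient": patient,
                "n_wells": len(results[patient]),
                "kras_altered": kras_alt,
                "tp53_altered": tp53_alt,
                "call": (
                    "KRAS_TP53"
                    if kras_alt and tp53_alt
                    else "KRAS_ONLY" if kras_alt else "OTHER"
                ),
            }
        )
    calls = pd.DataFrame(
        rows, columns=["patient", "n_wells", "kras_altered", "tp53_altered", "call"]
    )
    calls.to_csv(out / "ddpcr_calls.tsv", sep="\t", index=False)
    summary = {
        "n_patients": len(calls),
        "n_kras_only": int((calls["call"] == "KRAS_ONLY").sum()) if len(calls) else 0,
        "n_kras_tp53": int((calls["call"] == "KRAS_TP53").sum()) if len(calls) else 0,
        "n_other": int((calls["call"] == "OTHER").sum()) if len(calls) else 0,
    }
    (out / "ddpcr_summary.json").write_text(json.dumps(summary, indent=2))
    if not len(calls):
        log.warning("empty ddPCR batch: no droplet files or droplets")
    return calls
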