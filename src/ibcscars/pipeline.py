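"""Pipeline orchestration: segments + variants + clinical -> report bundle.

Stages run in method order (scores, recurrence, CTLP, variant filtering,
cohort statistics); stages whose inputs are missing are skipped with a
notice, and any stage error leaves the partial outputs in place with a
MANIFEST noting the failure point.  Logs go to stderr; machine outputs
(TSV/JSON) are never mixed with logs.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .ctlp import detect_ctlp, summarize_ctlp
from .genome import read_cytoband, read_segments
from .scars import cohort_recurrence, dichotomize_cohort, score_sample, scores_to_frame
from .stats import association_test, build_cohort_table, km_logrank, spearman_correlation
from .variants import (
    filter_variant,
    read_variant_table,
    summarize_cohort,
    PanelConfig,
)

logger = logging.getLogger("ibcscars")


def _setup_logging() -> None:
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage whose inputs exist; return the manifest dict."""
    _setup_logging()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.describe(),
        "stages": {},
        "failure": None,
    }
    report_lines = [f"ibcscars {__version__} report", ""]
    stage = "init"
    try:
        scores_df = None
        ctlp_by_sample = None
        if config.segments is not None and config.cytoband is not None:
            stage = "score"
            build = read_cytoband(config.cytoband)
            profiles = read_segments(config.segments, config.dialect)
            params = config.scar_params()
            scores = [score_sample(p, build, params) for p in profiles]
            if len(scores) >= 2:
                dichotomize_cohort(scores)
            scores_df = scores_to_frame(scores)
            scores_df.to_csv(out / "scores.tsv", sep="\t", index=False)
            cohort_json = {
                "n_samples": len(scores),
                "medians": {
                    k: float(scores_df[k].median())
                    for k in ("gii", "tai", "lst", "hrd_loh", "hrd_sum")
                },
                "high_counts": {
                    k: int(scores_df[k].sum())
                    for k in ("lst_high", "hrd_loh_high", "hrd_sum_high")
                },
                "hrd_loh_mode": params.hrd_loh_mode,
            }
            with open(out / "cohort_scores.json", "w") as fh:
                json.dump(cohort_json, fh, indent=1)
            manifest["stages"]["score"] = "ok"
            report_lines += [
                f"scores: {len(scores)} samples "
                f"(median HRD-sum {cohort_json['medians']['hrd_sum']:g})"
            ]
            _log("score", f"{len(scores)} samples scored")

            stage = "recurrence"
            track = cohort_recurrence(
                profiles, build,
                bin_size=config.overrides.get("recurrence_bin_size", 1_000_000),
                params=params,
            )
            track.bins.to_csv(out / "recurrence.tsv", sep="\t", index=False)
            manifest["stages"]["recurrence"] = "ok"

            stage = "ctlp"
            cparams = config.ctlp_params()
            ctlp_by_sample = {p.sample: detect_ctlp(p, build, cparams) for p in profiles}
            rows = [
                {
                    "sample": e.sample, "chrom": e.chrom, "start": e.start,
                    "end": e.end, "breakpoints": e.breakpoint_count,
                    "log10_lr": round(e.log10_lr, 3),
                    "altered_fraction": round(e.altered_fraction, 4),
                }
                for evs in ctlp_by_sample.values()
                for e in evs
            ]
            pd.DataFrame(
                rows,
                columns=["sample", "chrom", "start", "end", "breakpoints",
                         "log10_lr", "altered_fraction"],
            ).to_csv(out / "ctlp.tsv", sep="\t", index=False)
            manifest["stages"]["ctlp"] = "ok"
            report_lines += [f"ctlp: {len(rows)} events"]
            _log("ctlp", f"{len(rows)} events detected")

            if scores_df is not None and "gii_high" in scores_df:
                assoc = summarize_ctlp(
                    ctlp_by_sample,
                    dict(zip(scores_df["sample"], scores_df["gii_high"])),
                )
                with open(out / "ctlp_vs_gii.json", "w") as fh:
                    json.dump(
                        {
                            "p": assoc.get("p"),
                            "notice": assoc.get("notice"),
                            "table": assoc["table"].to_dict(),
                        },
                        fh, indent=1,
                    )
        else:
            manifest["stages"]["score"] = "skipped: segments/cytoband missing"
            _log("score", "skipped (no segments/cytoband)")

        summary = None
        if config.variants is not None:
            stage = "filter"
            records = read_variant_table(config.variants)
            decisions = [filter_variant(r) for r in records]
            fdf = pd.DataFrame(
                {
                    "sample": [r.sample for r in records],
                    "gene": [r.gene for r in records],
                    "hgvs_c": [r.hgvs_c for r in records],
                    "verdict": [d.verdict for d in decisions],
                    "rule_fired": [d.rule_fired for d in decisions],
                    "rationale": [d.rationale for d in decisions],
                }
            )
            fdf.to_csv(out / "variants_filtered.tsv", sep="\t", index=False)
            kept = fdf[fdf["verdict"] == "keep"]
            manifest["stages"]["filter"] = "ok"
            _log("filter", f"{len(kept)}/{len(fdf)} variants kept")

            stage = "summarize"
            if len(kept):
                summary = summarize_cohort(kept, PanelConfig.default())
                with open(out / "variant_summary.json", "w") as fh:
                    json.dump(
                        {
                            "gene_case_counts": summary.gene_case_counts.to_dict(),
                            "pathway_case_counts": summary.pathway_case_counts,
                            "n_samples": summary.n_samples,
                        },
                        fh, indent=1,
                    )
            manifest["stages"]["summarize"] = "ok"
        else:
            manifest["stages"]["filter"] = "skipped: variants missing"
            _log("filter", "skipped (no variant table)")

        if config.clinical is not None:
            stage = "cohort"
            from .stats import read_clinical_table

            clinical = read_clinical_table(config.clinical)
            label_cols = None
            if scores_df is not None:
                label_cols = scores_df[
                    ["sample", "gii_high", "tai_high", "lst_high",
                     "hrd_loh_high", "hrd_sum_high"]
                ]
            table = build_cohort_table(
                clinical,
                scores=label_cols,
                pathway_status=summary.sample_pathway_status if summary else None,
                ctlp_samples={
                    s for s, evs in (ctlp_by_sample or {}).items() if evs
                }
                if ctlp_by_sample is not None
                else None,
            )
            table.to_csv(out / "cohort_table.tsv", sep="\t", index=False)
            stats_out: dict = {}
            if "tai_high" in table and table["tai_high"].notna().all():
                group = table["tai_high"].map({True: "high", False: "low"})
                if group.nunique() == 2:
                    _, stat, p = km_logrank(
                        table.assign(tai_group=group), "tai_group"
                    )
                    stats_out["os_by_tai"] = {"logrank": stat, "p": p}
            with open(out / "cohort_stats.json", "w") as fh:
                json.dump(stats_out, fh, indent=1)
            manifest["stages"]["cohort"] = "ok"
            _log("cohort", "cohort statistics written")
        else:
            manifest["stages"]["cohort"] = "skipped: clinical table missing"
            _log("cohort", "skipped (no clinical table)")
    except Exception as exc:
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    report_lines += ["", "stages: " + ", ".join(
        f"{k}={v}" for k, v in manifest["stages"].items()
    )]
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
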