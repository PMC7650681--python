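"""Run configuration: every tunable threshold in one place.

Each default that is a stated constant of the underlying method is marked
``method constant`` and must never drift silently; the remaining defaults
are this package's own choices (marked ``package default``).  The CLI's
``print-defaults`` command lists them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

from .ctlp import CTLPParams
from .scars import ScarParams

#: (name, value, kind, meaning) for every tunable threshold
DEFAULTS: list[tuple[str, object, str, str]] = [
    ("rare_af_max", 0.01, "method constant",
     "population-frequency ceiling for a variant to count as rare (<0.01)"),
    ("lst_min_flank", 10_000_000, "method constant",
     "minimum flank size (bp) on both sides of a large-scale state transition"),
    ("lst_high_diploid_above", 15, "method constant",
     "LST high cut-off in diploid tumors (strictly above)"),
    ("lst_high_polyploid_above", 20, "method constant",
     "LST high cut-off in polyploid tumors (strictly above)"),
    ("hrd_loh_min_size", 15_000_000, "method constant",
     "minimum LOH tract size (bp, strictly above) for the HRD-LOH score"),
    ("hrd_loh_high_at_least", 10, "method constant",
     "HRD-LOH high cut-off (at least)"),
    ("hrd_sum_high_at_least", 42, "method constant",
     "HRD-sum high cut-off (at least)"),
    ("ctlp_lr_min", 8.0, "method constant",
     "minimum log10 likelihood ratio for a chromothripsis-like region"),
    ("ctlp_bp_min", 10, "method constant",
     "breakpoint count a region must strictly exceed"),
    ("ctlp_seg_min", 10_000, "method constant",
     "minimum segment size (bp) retained before breakpoint counting"),
    ("ctlp_signal_dist", 0.1, "method constant",
     "minimum log2 copy-number distance between adjacent segments"),
    ("ctlp_altered_min", 0.10, "method constant",
     "fraction of the region at non-baseline CN a region must strictly exceed"),
    ("recurrent_gain_loss_above", 0.50, "method constant",
     "cohort fraction a gain/loss must strictly exceed to be recurrent"),
    ("recurrent_cnloh_at_least", 0.25, "method constant",
     "cohort fraction at which cnLOH is recurrent (at least)"),
    ("alpha", 0.05, "method constant",
     "significance level (p <= alpha)"),
    ("baseline_cn", 2, "method constant",
     "diploid baseline copy number (defines CNA and cnLOH)"),
    ("pg_vaf_below", 0.5, "method constant",
     "potentially-germline flag: VAF strictly below this value"),
    ("telomere_tol", 1_000, "package default",
     "bp slack for a segment to count as reaching the telomere"),
    ("tai_min_size", 0, "package default",
     "minimum size (bp) of a telomeric allelic-imbalance segment"),
    ("lst_smooth_below", 3_000_000, "package default",
     "segments shorter than this (bp) are absorbed before LST counting"),
    ("lst_max_gap", 3_000_000, "package default",
     "maximum uncovered gap (bp) between the two LST flanks"),
    ("hrd_loh_mode", "cnloh", "package default",
     "which LOH tracts HRD-LOH counts: cnloh (as defined) or any_loh"),
    ("ploidy_polyploid_above", 2.5, "package default",
     "length-weighted mean CN above which a sample is called polyploid"),
    ("include_sex_chromosomes", False, "package default",
     "whether scar scores include chrX/chrY"),
    ("recurrence_bin_size", 1_000_000, "package default",
     "genomic bin size (bp) for cohort recurrence tracks"),
]


@dataclass
class RunConfig:
    """Paths, seed and threshold overrides for the full pipeline."""

    segments: Optional[Path] = None
    cytoband: Optional[Path] = None
    variants: Optional[Path] = None
    clinical: Optional[Path] = None
    out_dir: Path = Path("ibcscars_out")
    seed: int = 0
    dialect: str = "seg-1-based-inclusive"
    overrides: dict = field(default_factory=dict)

    def scar_params(self) -> ScarParams:
        kw = {
            f.name: self.overrides[f.name]
            for f in fields(ScarParams)
            if f.name in self.overrides
        }
        return ScarParams(**kw)

    def ctlp_params(self) -> CTLPParams:
        mapping = {
            "ctlp_lr_min": "lr_min",
            "ctlp_bp_min": "bp_min",
            "ctlp_seg_min": "seg_min",
            "ctlp_signal_dist": "signal_dist",
            "ctlp_altered_min": "altered_min",
        }
        kw = {
            target: self.overrides[name]
            for name, target in mapping.items()
            if name in self.overrides
        }
        return CTLPParams(**kw)

    def describe(self) -> list[dict]:
        out = []
        for name, value, kind, meaning in DEFAULTS:
            out.append(
                {
                    "parameter": name,
                    "default": value,
                    "override": self.overrides.get(name),
                    "kind": kind,
                    "meaning": meaning,
                }
            )
        return out
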