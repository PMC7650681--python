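"""Synthetic inputs with known ground truth for every pipeline stage.

The generator targets the detectors' contracts, not tumor biology: each
planted event is placed with margins at least twice the relevant
detection threshold, so the scar scores, the CTLP scanner and the variant
cascade must recover the planted truth *exactly* — parameter recovery is
a sharp test, not a statistical one.

Planted event shapes (background is diploid heterozygous (2,1)):

* TAI event    — terminal allelic-imbalance segment, state (3,1), 5-8 Mb,
  placed flush against a chromosome end; never crosses the centromere.
* LST event    — a 12 Mb (3,1) segment touching a 12 Mb (2,1) segment,
  the pair insulated from the background by 4 Mb uncovered gaps, so the
  single internal junction is the only qualifying break.
* LOH event    — interstitial copy-neutral LOH tract (2,0), 17 Mb,
  insulated by 4 Mb gaps (no large-scale transition, no total-CN
  breakpoint).
* GII filler   — gap-insulated balanced (2.1, 1.05) blocks that raise the
  altered genome fraction to the requested target; their CN offset sits
  below the CTLP signal distance on the log2 scale and the insulating
  gaps exceed the LST flank gap, so no detector sees them.
* CTLP event   — run of alternating total-CN segments (balanced minor) on
  one chromosome, >= 1 Mb each, producing an exact number of breakpoints.

Determinism: identical (parameters, seed) give byte-identical outputs;
per-sample child seeds derive from the master seed by fixed offset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import CN_TOL, GenomeBuild, Chromosome, Segment, SegmentProfile, profile_from_segments
from .variants import PanelConfig, VariantRecord

__all__ = [
    "SimulationTruth",
    "make_toy_build",
    "simulate_profile",
    "simulate_ctlp_chromosome",
    "simulate_variant_table",
    "simulate_cohort",
    "child_seed",
]

# event geometry (bp); margins >= 2x the detection thresholds they defeat
_TAI_LEN_RANGE = (5_000_000, 8_000_000)
_TAI_STATE = (3.0, 1.0)
_LST_FLANK = 12_000_000
_LST_STATES = ((3.0, 1.0), (2.0, 1.0))
_LOH_LEN = 17_000_000
_LOH_STATE = (2.0, 0.0)
_EVENT_GAP = 4_000_000          # uncovered insulation, > LST max gap (3 Mb)
_GII_STATE = (2.1, 1.05)        # |log2(2.1/2)| ~= 0.07 < CTLP signal 0.1
_TERMINAL_RESERVE = 12_000_000  # interior events keep clear of chromosome ends
_CEN_MARGIN = 1_000_000
_BACKGROUND = (2.0, 1.0)


def child_seed(master_seed: int, index: int) -> np.random.Generator:
    """Per-sample generator derived from the master seed by fixed offset."""
    return np.random.default_rng([int(master_seed), int(index)])


@dataclass
class SimulationTruth:
    """Ground truth serialized alongside every simulated dataset."""

    master_seed: int
    kind: str                    # profile | ctlp | variants | cohort
    params: dict
    truth: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_toy_build(
    n_chrom: int = 3,
    chrom_len: int = 100_000_000,
    centromere_at: float = 0.5,
) -> GenomeBuild:
    """Uniform toy genome with centered 2 Mb centromeres."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    mid = int(chrom_len * centromere_at)
    chroms = tuple(
        Chromosome(
            name=f"chr{i + 1}",
            length=chrom_len,
            centromere=(mid - 1_000_000, mid + 1_000_000),
        )
        for i in range(n_chrom)
    )
    return GenomeBuild(name=f"toy{n_chrom}x{chrom_len // 1_000_000}Mb", chromosomes=chroms)


# ---------------------------------------------------------------------------
# scar-score profiles
# ---------------------------------------------------------------------------

@dataclass
class _Placed:
    chrom: str
    start: int
    end: int
    kind: str                   # tai | lst | loh | gii | gap | noise
    segments: list[tuple[int, int, float, Optional[float]]] = field(default_factory=list)


def _interior_windows(build: GenomeBuild) -> list[tuple[str, int, int]]:
    windows = []
    for c in build.chromosomes:
        cen = c.centromere or (c.length // 2, c.length // 2)
        p = (_TERMINAL_RESERVE, cen[0] - _CEN_MARGIN)
        q = (cen[1] + _CEN_MARGIN, c.length - _TERMINAL_RESERVE)
        for s, e in (p, q):
            if e - s > 0:
                windows.append((c.name, s, e))
    return windows


def simulate_profile(
    build: GenomeBuild,
    n_tai: int = 4,
    n_lst: int = 3,
    n_loh: int = 2,
    gii_target: float = 0.363,
    noise: float = 0.0,
    seed: int = 0,
    sample: str = "SIM",
) -> tuple[SegmentProfile, SimulationTruth]:
    """Plant exactly *n_tai* / *n_lst* / *n_loh* scar events plus GII filler.

    Events are pairwise disjoint with margins >= 2x every detection
    threshold; infeasible packings raise with the genome size required.
    ``noise`` (max |CN deviation|, <= 0.05) adds sub-3 Mb balanced jitter
    pieces inside background segments; they sit below every detection
    threshold but do count toward the altered fraction, which the truth
    records exactly.
    """
    if not 0 <= noise <= 0.05:
        raise ValueError("noise must be in [0, 0.05] to stay below all thresholds")
    if not 0 <= gii_target < 1:
        raise ValueError("gii_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    placed: list[_Placed] = []

    # --- terminal TAI slots -------------------------------------------------
    slots = [(c.name, arm) for c in build.chromosomes for arm in ("p", "q")]
    if n_tai > len(slots):
        raise ValueError(
            f"cannot place {n_tai} TAI events: only {len(slots)} chromosome "
            f"ends; use a build with >= {int(np.ceil(n_tai / 2))} chromosomes"
        )
    order = rng.permutation(len(slots))
    for idx in order[:n_tai]:
        chrom, arm = slots[idx]
        length = int(rng.integers(*_TAI_LEN_RANGE))
        c = build[chrom]
        if arm == "p":
            start, end = 0, length
        else:
            start, end = c.length - length, c.length
        placed.append(
            _Placed(chrom, start, end, "tai", [(start, end, *_TAI_STATE)])
        )

    # --- interior events (LST pairs, LOH tracts) ----------------------------
    windows = _interior_windows(build)
    cursors = {i: w[1] for i, w in enumerate(windows)}
    win_order = list(rng.permutation(len(windows)))

    def place_interior(footprint: int) -> tuple[str, int]:
        for _ in range(len(windows)):
            i = win_order[0]
            win_order.append(win_order.pop(0))
            chrom, _s, e = windows[i]
            jitter = int(rng.integers(0, 2_000_000))
            start = cursors[i] + jitter
            if start + footprint <= e:
                cursors[i] = start + footprint
                return chrom, start
        raise ValueError(
            f"cannot place event of {footprint} bp: genome too small; "
            f"need at least {footprint + 2 * _TERMINAL_RESERVE} bp of free arm"
        )

    for _ in range(n_lst):
        foot = 2 * _EVENT_GAP + 2 * _LST_FLANK
        chrom, s = place_interior(foot)
        a0 = s + _EVENT_GAP
        a1 = a0 + _LST_FLANK
        b1 = a1 + _LST_FLANK
        placed.append(
            _Placed(
                chrom, s, s + foot, "lst",
                [
                    (a0, a1, *_LST_STATES[0]),
                    (a1, b1, *_LST_STATES[1]),
                ],
            )
        )
    for _ in range(n_loh):
        foot = 2 * _EVENT_GAP + _LOH_LEN
        chrom, s = place_interior(foot)
        t0 = s + _EVENT_GAP
        placed.append(
            _Placed(chrom, s, s + foot, "loh", [(t0, t0 + _LOH_LEN, *_LOH_STATE)])
        )

    # --- GII filler blocks ---------------------------------------------------
    # Gap-insulated altered blocks of arbitrary length; each block adds
    # 2 x _EVENT_GAP of uncovered genome, so the needed altered length is
    # re-derived from the running covered length after every placement.
    total_len = sum(c.length for c in build.chromosomes)
    gaps = sum(
        (p.end - p.start) - sum(e - s for s, e, *_ in p.segments) for p in placed
    )
    altered = sum(
        e - s
        for p in placed
        for (s, e, tot, _m) in p.segments
        if abs(tot - 2.0) > CN_TOL
    )
    while True:
        covered = total_len - gaps
        # size the block against the covered length it will leave behind;
        # stop once the shortfall is within the gap-induced granularity
        extra = int(round(gii_target * (covered - 2 * _EVENT_GAP))) - altered
        if extra < 100_000:
            break
        best = max(range(len(windows)), key=lambda i: windows[i][2] - cursors[i])
        chrom, _ws, we = windows[best]
        jitter = int(rng.integers(0, 2_000_000))
        room = we - cursors[best] - jitter - 2 * _EVENT_GAP
        block = min(extra, room)
        if block < 100_000:
            raise ValueError(
                f"genome too small to reach gii_target={gii_target}; "
                f"need roughly {extra} more bp of free arm"
            )
        s = cursors[best] + jitter
        g0 = s + _EVENT_GAP
        foot = 2 * _EVENT_GAP + block
        placed.append(
            _Placed(chrom, s, s + foot, "gii", [(g0, g0 + block, *_GII_STATE)])
        )
        cursors[best] = s + foot
        altered += block
        gaps += 2 * _EVENT_GAP

    _audit_disjoint(placed)

    # --- assemble per-chromosome segment lists -------------------------------
    segments: list[Segment] = []
    for c in build.chromosomes:
        events = sorted((p for p in placed if p.chrom == c.name), key=lambda p: p.start)
        pos = 0
        for ev in events:
            if ev.start > pos:
                segments.append(Segment(c.name, pos, ev.start, *_BACKGROUND))
            for (s, e, tot, minor) in ev.segments:
                segments.append(Segment(c.name, s, e, tot, minor))
            pos = ev.end
        if pos < c.length:
            segments.append(Segment(c.name, pos, c.length, *_BACKGROUND))

    if noise > 0:
        segments = _inject_noise(segments, noise, rng)

    profile = profile_from_segments(sample, segments)

    # exact altered fraction of the final profile (independent arithmetic)
    alt = sum(s.length for s in profile if abs(s.total_cn - 2.0) > CN_TOL)
    cov = sum(s.length for s in profile)
    truth = SimulationTruth(
        master_seed=int(seed),
        kind="profile",
        params={
            "n_tai": n_tai, "n_lst": n_lst, "n_loh": n_loh,
            "gii_target": gii_target, "noise": noise, "build": build.name,
            "sample": sample,
        },
        truth={
            "n_tai": n_tai,
            "n_lst": n_lst,
            "n_loh": n_loh,
            "gii": alt / cov,
            "events": [
                {"chrom": p.chrom, "start": p.start, "end": p.end, "kind": p.kind}
                for p in placed
            ],
        },
    )
    return profile, truth


def _audit_disjoint(placed: Sequence[_Placed]) -> None:
    """Re-verify that no two planted footprints overlap (generator bug guard)."""
    by_chrom: dict[str, list[_Placed]] = {}
    for p in placed:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda p: p.start)
        for a, b in zip(evs, evs[1:]):
            if a.end > b.start:
                raise AssertionError(
                    f"planted events overlap on {chrom}: "
                    f"[{a.start},{a.end}) vs [{b.start},{b.end})"
                )


def _inject_noise(
    segments: list[Segment], noise: float, rng: np.random.Generator
) -> list[Segment]:
    """Carve short balanced jitter pieces out of long background segments."""
    out: list[Segment] = []
    for seg in segments:
        is_bg = (
            abs(seg.total_cn - _BACKGROUND[0]) <= CN_TOL
            and seg.minor_cn is not None
            and abs(seg.minor_cn - _BACKGROUND[1]) <= CN_TOL
        )
        if not is_bg or seg.length < 10_000_000 or rng.random() > 0.5:
            out.append(seg)
            continue
        piece = int(rng.integers(1_000_000, 2_500_000))
        off = int(rng.integers(3_500_000, seg.length - piece - 3_500_000))
        delta = round(float(rng.uniform(0.02, noise)), 4) * (1 if rng.random() < 0.5 else -1)
        total = round(2.0 + delta, 4)
        mid0 = seg.start + off
        out.append(Segment(seg.chrom, seg.start, mid0, *_BACKGROUND))
        out.append(Segment(seg.chrom, mid0, mid0 + piece, total, total / 2))
        out.append(Segment(seg.chrom, mid0 + piece, seg.end, *_BACKGROUND))
    return out


# ---------------------------------------------------------------------------
# CTLP chromosomes
# ---------------------------------------------------------------------------

def simulate_ctlp_chromosome(
    build: GenomeBuild,
    chrom: str,
    n_switches: int,
    low_cn: float = 1.0,
    high_cn: float = 2.0,
    span: int = 28_000_000,
    seed: int = 0,
    start: Optional[int] = None,
    sample: str = "SIM",
) -> tuple[SegmentProfile, SimulationTruth]:
    """Oscillating chromosome fragment with exactly *n_switches* junctions.

    The fragment alternates between *low_cn* and *high_cn* over
    ``n_switches + 1`` segments of >= 1 Mb within *span*; minor CN is kept
    balanced (total / 2) so the fragment exercises only the total-CN
    oscillation detector.  The profile covers only the fragment.
    """
    if n_switches < 2:
        raise ValueError("n_switches must be >= 2")
    n_seg = n_switches + 1
    seg_len = span // n_seg
    if seg_len < 1_000_000:
        raise ValueError(
            f"span {span} too small for {n_seg} segments of >= 1 Mb; "
            f"need span >= {n_seg * 1_000_000}"
        )
    c = build[chrom]
    if start is None:
        cen = c.centromere or (0, 0)
        start = cen[1] + 1_000_000
    if start + span > c.length:
        raise ValueError(f"span does not fit chromosome {chrom}")
    segs = []
    for i in range(n_seg):
        s = start + i * seg_len
        e = start + span if i == n_seg - 1 else s + seg_len
        cn = low_cn if i % 2 == 0 else high_cn
        segs.append(Segment(chrom, s, e, cn, cn / 2))
    profile = profile_from_segments(sample, segs)
    truth = SimulationTruth(
        master_seed=int(seed),
        kind="ctlp",
        params={
            "chrom": chrom, "n_switches": n_switches, "low_cn": low_cn,
            "high_cn": high_cn, "span": span, "sample": sample,
        },
        truth={
            "regions": [{"chrom": chrom, "start": start, "end": start + span,
                         "breakpoints": n_switches}],
        },
    )
    return profile, truth


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

#: planted-class -> intended cascade verdict
CLASS_VERDICTS = {
    "PLP": "keep",
    "VUS_LOF": "keep",
    "VUS_other": "drop",
    "common": "drop",
    "synonymous": "drop",
    "intronic": "drop",
}

DEFAULT_CLASS_MIX = {
    "PLP": 0.20,
    "VUS_LOF": 0.10,
    "VUS_other": 0.25,
    "common": 0.20,
    "synonymous": 0.15,
    "intronic": 0.10,
}


def _draw_hgvs(rng: np.random.Generator) -> tuple[str, str]:
    bases = "ACGT"
    pos = int(rng.integers(1, 5000))
    ref, alt = rng.choice(list(bases), size=2, replace=False)
    return f"c.{pos}{ref}>{alt}", f"p.Xaa{1 + pos // 3}Yaa"


def simulate_variant_table(
    n_samples: int = 21,
    class_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    panel: Optional[PanelConfig] = None,
    hr_enrichment: float = 0.3,
    mean_variants_per_sample: float = 5.0,
) -> tuple[list[VariantRecord], SimulationTruth]:
    """Annotated variant records with planted cascade verdicts.

    Genes are drawn from the 105-gene panel, HR/MMR genes with probability
    *hr_enrichment*.  The truth carries the intended keep/drop verdict for
    every record, in order.
    """
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    unknown = set(mix) - set(CLASS_VERDICTS)
    if unknown:
        raise ValueError(f"unknown classes {sorted(unknown)}")
    panel = panel or PanelConfig.default()
    pathway_genes = sorted(panel.hr_genes | panel.mmr_genes)
    other_genes = sorted(panel.panel - set(pathway_genes))
    rng = np.random.default_rng(seed)
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes])
    records: list[VariantRecord] = []
    verdicts: list[str] = []
    for i in range(n_samples):
        srng = child_seed(seed, i)
        n_var = int(srng.poisson(mean_variants_per_sample))
        for _ in range(n_var):
            cls = classes[int(srng.choice(len(classes), p=probs))]
            if srng.random() < hr_enrichment:
                gene = pathway_genes[int(srng.integers(len(pathway_genes)))]
            else:
                gene = other_genes[int(srng.integers(len(other_genes)))]
            hgvs_c, hgvs_p = _draw_hgvs(srng)
            vaf = float(srng.uniform(0.05, 0.95))
            rare = (
                {}
                if srng.random() < 0.5
                else {"gnomad": float(srng.uniform(0, 0.009))}
            )
            consequence, region, pop_af, clin = "missense", "exonic", rare, {}
            if cls == "PLP":
                consequence = ["missense", "stopgain", "frameshift"][
                    int(srng.integers(3))
                ]
                source = ["acmg", "clinvar", "clinvitae"][int(srng.integers(3))]
                clin = {source: ["pathogenic", "likely_pathogenic"][int(srng.integers(2))]}
            elif cls == "VUS_LOF":
                consequence = ["frameshift", "stopgain", "canonical_splice"][
                    int(srng.integers(3))
                ]
                clin = {"acmg": "vus"}
            elif cls == "VUS_other":
                consequence = ["missense", "inframe_indel"][int(srng.integers(2))]
                clin = {"acmg": "vus"}
            elif cls == "common":
                pop_af = {"gnomad": float(srng.uniform(0.01, 0.2))}
                if srng.random() < 0.3:   # clinical evidence must not rescue it
                    clin = {"clinvar": "pathogenic"}
            elif cls == "synonymous":
                consequence = "synonymous"
            elif cls == "intronic":
                consequence = "other"
                region = "intronic"
            records.append(
                VariantRecord(
                    sample=f"S{i + 1}",
                    gene=gene,
                    hgvs_c=hgvs_c,
                    hgvs_p=hgvs_p,
                    consequence=consequence,
                    region=region,
                    vaf=vaf,
                    pop_af=pop_af,
                    clin_class=clin,
                )
            )
            verdicts.append(CLASS_VERDICTS[cls])
    truth = SimulationTruth(
        master_seed=int(seed),
        kind="variants",
        params={
            "n_samples": n_samples, "class_mix": mix,
            "hr_enrichment": hr_enrichment,
            "mean_variants_per_sample": mean_variants_per_sample,
        },
        truth={"verdicts": verdicts},
    )
    return records, truth


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def _uniform_censor_max(lam: float, censor_frac: float) -> float:
    """c such that P(U(0,c) < Exp(lam)) = censor_frac."""
    from scipy.optimize import brentq

    def frac(c: float) -> float:
        return (1.0 - np.exp(-lam * c)) / (lam * c)

    return float(brentq(lambda c: frac(c) - censor_frac, 1e-9 / lam, 1e6 / lam))


def simulate_cohort(
    n_per_arm: int = 100,
    hazard_ratio: float = 2.5,
    censor_frac: float = 0.2,
    seed: int = 0,
    median_os_arm1: float = 25.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Two-arm survival cohort with exponential event times.

    Arm 2's hazard is *hazard_ratio* times arm 1's; arm 1's median OS
    defaults to 25 months, the scale of the cohort this package targets.
    Censoring is independent uniform, calibrated so the expected censored
    fraction equals *censor_frac* in each arm.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    lam1 = np.log(2.0) / median_os_arm1
    rows = []
    for arm_idx, lam in enumerate((lam1, lam1 * hazard_ratio)):
        rng = child_seed(seed, arm_idx)
        t = rng.exponential(scale=1.0 / lam, size=n_per_arm)
        if censor_frac > 0:
            cmax = _uniform_censor_max(lam, censor_frac)
            c = rng.uniform(0, cmax, size=n_per_arm)
            obs = np.minimum(t, c)
            event = t <= c
        else:
            obs = t
            event = np.ones(n_per_arm, dtype=bool)
        subtype = rng.choice(
            ["HRpos_HER2neg", "HRneg_HER2pos", "TNBC"],
            size=n_per_arm,
            p=[0.53, 0.15, 0.32],
        )
        metastasis = rng.choice(
            ["none", "at_diagnosis", "follow_up"],
            size=n_per_arm,
            p=[0.24, 0.38, 0.38],
        )
        for i in range(n_per_arm):
            rows.append(
                {
                    "sample": f"A{arm_idx + 1}_{i + 1}",
                    "arm": f"arm{arm_idx + 1}",
                    "subtype": subtype[i],
                    "metastasis": metastasis[i],
                    "os_months": round(float(obs[i]), 6),
                    "event": "death" if event[i] else "censored",
                }
            )
    truth = SimulationTruth(
        master_seed=int(seed),
        kind="cohort",
        params={
            "n_per_arm": n_per_arm, "hazard_ratio": hazard_ratio,
            "censor_frac": censor_frac, "median_os_arm1": median_os_arm1,
        },
        truth={"hazard_ratio": hazard_ratio},
    )
    return pd.DataFrame(rows), truth
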