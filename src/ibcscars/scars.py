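"""Genomic-scar statistics: GII, TAI, LST, HRD-LOH and the combined HRD sum.

These are the array-based homologous-recombination-deficiency signatures:

* **GII** — fraction of the covered genome whose total copy number deviates
  from the diploid baseline (copy-neutral LOH does not count).
* **TAI** — number of subtelomeric allelic-imbalance segments that reach a
  telomere without crossing the centromere (at most one per arm).
* **LST** — number of chromosomal breaks between adjacent copy-number
  regions of at least 10 Mb, after smoothing away sub-3 Mb fragments.
* **HRD-LOH** — number of long (>15 Mb) sub-chromosomal LOH tracts,
  copy-neutral by default.
* **HRD-sum** — the unweighted sum TAI + LST + HRD-LOH.

Fixed high/low cut-offs follow the published method: LST high above 15 in
diploid and above 20 in polyploid tumors, HRD-LOH high at >=10, HRD-sum high
at >=42.  GII and TAI are dichotomized at the cohort median (strictly above
the median is "high").  Sex chromosomes are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    BASELINE_CN,
    CN_TOL,
    GenomeBuild,
    Segment,
    SegmentProfile,
    SEX_CHROMOSOMES,
)

__all__ = [
    "ScarParams",
    "ScarScores",
    "RecurrenceTrack",
    "compute_gii",
    "estimate_ploidy",
    "compute_tai",
    "compute_lst",
    "compute_hrd_loh",
    "score_sample",
    "dichotomize_cohort",
    "cohort_recurrence",
    "smooth_segments",
]


@dataclass(frozen=True)
class ScarParams:
    """Tunable thresholds; defaults are the published constants where stated."""

    baseline_cn: int = BASELINE_CN
    include_sex_chromosomes: bool = False
    telomere_tol: int = 1_000                # bp slack for "reaches the telomere"
    tai_min_size: int = 0
    lst_smooth_below: int = 3_000_000
    lst_min_flank: int = 10_000_000          # stated: breaks between >=10 Mb regions
    lst_max_gap: int = 3_000_000
    hrd_loh_mode: str = "cnloh"              # "cnloh" (as worded) or "any_loh"
    hrd_loh_min_size: int = 15_000_000       # stated: larger than 15 Mb
    ploidy_polyploid_above: float = 2.5
    lst_high_diploid_above: int = 15         # stated: high >15 in diploid
    lst_high_polyploid_above: int = 20       # stated: high >20 in polyploid
    hrd_loh_high_at_least: int = 10          # stated: high >=10
    hrd_sum_high_at_least: int = 42          # stated: high >=42


@dataclass
class ScarScores:
    sample: str
    gii: float
    tai: int
    lst: int
    hrd_loh: int
    hrd_sum: int
    ploidy: float
    ploidy_class: str                        # "diploid" | "polyploid"
    lst_high: bool
    hrd_loh_high: bool
    hrd_sum_high: bool
    #: segments skipped by TAI/HRD-LOH because minor_cn was missing
    n_missing_minor: int = 0
    #: cohort-relative labels, filled by dichotomize_cohort
    gii_high: Optional[bool] = None
    tai_high: Optional[bool] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.hrd_sum == self.tai + self.lst + self.hrd_loh
        assert 0.0 <= self.gii <= 1.0


def _included_chroms(profile: SegmentProfile, params: ScarParams) -> list[str]:
    chroms = profile.chromosomes
    if not params.include_sex_chromosomes:
        chroms = [c for c in chroms if c not in SEX_CHROMOSOMES]
    return chroms


# ---------------------------------------------------------------------------
# GII and ploidy
# ---------------------------------------------------------------------------

def compute_gii(
    profile: SegmentProfile,
    build: GenomeBuild | None = None,
    params: ScarParams = ScarParams(),
) -> float:
    """Fraction of the covered genome with total CN away from baseline.

    The denominator is the covered length (sum of segment lengths), not the
    physical chromosome length; copy-neutral LOH does not contribute.
    """
    chroms = _included_chroms(profile, params)
    covered = profile.covered_length(chroms)
    if covered == 0:
        raise ValueError(f"sample {profile.sample}: empty profile")
    altered = sum(
        s.length
        for c in chroms
        for s in profile.segments_of(c)
        if abs(s.total_cn - params.baseline_cn) > CN_TOL
    )
    return altered / covered


def estimate_ploidy(
    profile: SegmentProfile, params: ScarParams = ScarParams()
) -> tuple[float, str]:
    """Length-weighted mean total CN and a diploid/polyploid call (strict >2.5)."""
    chroms = _included_chroms(profile, params)
    segs = [s for c in chroms for s in profile.segments_of(c)]
    if not segs:
        raise ValueError(f"sample {profile.sample}: no segments with total_cn")
    total = sum(s.length for s in segs)
    ploidy = sum(s.total_cn * s.length for s in segs) / total
    cls = "polyploid" if ploidy > params.ploidy_polyploid_above else "diploid"
    return ploidy, cls


# ---------------------------------------------------------------------------
# TAI
# ---------------------------------------------------------------------------

def _require_minor(profile: SegmentProfile, what: str) -> None:
    if not profile.has_minor_cn():
        raise ValueError(
            f"sample {profile.sample}: allele-specific data required for {what}"
        )


def _overlaps(seg: Segment, start: int, end: int) -> bool:
    return seg.start < end and seg.end > start


def compute_tai(
    profile: SegmentProfile,
    build: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> tuple[int, int]:
    """Telomeric allelic-imbalance count.

    A segment qualifies when it is in allelic imbalance, reaches the
    terminal covered coordinate of its chromosome (within
    ``telomere_tol``), does not intersect the centromere, and has length
    >= ``tai_min_size``.  At most one segment counts per arm (two per
    chromosome).  Touching equal-state segments are merged first.
    Returns ``(count, n_missing_minor)``.
    """
    from .genome import normalize_profile

    _require_minor(profile, "TAI")
    profile = normalize_profile(profile)
    count = 0
    missing = 0
    for chrom in _included_chroms(profile, params):
        if chrom not in build:
            continue
        segs = profile.segments_of(chrom)
        if not segs:
            continue
        ext = profile.covered_extent(chrom)
        assert ext is not None
        cov_start, cov_end = ext
        cen = build[chrom].centromere
        p_hit = q_hit = False
        for seg in segs:
            if seg.minor_cn is None:
                missing += 1
                continue
            if not seg.allelic_imbalance or seg.length < params.tai_min_size:
                continue
            if cen is not None and _overlaps(seg, *cen):
                continue
            if seg.start <= cov_start + params.telomere_tol:
                p_hit = True
            if seg.end >= cov_end - params.telomere_tol:
                q_hit = True
        count += int(p_hit) + int(q_hit)
    return count, missing


# ---------------------------------------------------------------------------
# LST
# ---------------------------------------------------------------------------

def smooth_segments(segs: Sequence[Segment], min_len: int) -> list[Segment]:
    """Absorb segments shorter than *min_len* into their larger neighbour.

    Touching equal-state segments are merged first, so results are
    invariant under arbitrary splitting of segments into equal-state
    pieces.  Then, shortest-first, each remaining sub-threshold segment is
    absorbed by its larger neighbour (extended over the short segment,
    bridging any gap between them).  Shared by the LST smoothing step and
    the CTLP minimum-segment-size rule.
    """
    out: list[Segment] = []
    for s in segs:
        if out and out[-1].end >= s.start and out[-1].state() == s.state():
            out[-1] = replace(out[-1], end=s.end)
        else:
            out.append(s)
    while True:
        short = [
            (s.length, i) for i, s in enumerate(out) if s.length < min_len
        ]
        if not short or len(out) == 1:
            break
        _, i = min(short)
        left = out[i - 1] if i > 0 else None
        right = out[i + 1] if i + 1 < len(out) else None
        if left is not None and (right is None or left.length >= right.length):
            out[i - 1] = replace(left, end=out[i].end)
        else:
            assert right is not None
            out[i + 1] = replace(right, start=out[i].start)
        del out[i]
        # merge newly adjacent equal-state touching segments
        j = 1
        while j < len(out):
            a, b = out[j - 1], out[j]
            if a.end >= b.start and a.state() == b.state():
                out[j - 1] = replace(a, end=b.end)
                del out[j]
            else:
                j += 1
    return out


def _arm_segments(
    segs: Sequence[Segment], cen: Optional[tuple[int, int]], length: int
) -> list[list[Segment]]:
    """Split a chromosome's segments into per-arm lists.

    A segment belongs to the arm containing its midpoint; a segment
    spanning the whole centromere is included in both arms (it can serve
    as a flank on either side).
    """
    if cen is None:
        return [list(segs)]
    cen_s, cen_e = cen
    p: list[Segment] = []
    q: list[Segment] = []
    for seg in segs:
        if seg.start < cen_s and seg.end > cen_e:
            p.append(seg)
            q.append(seg)
            continue
        mid = (seg.start + seg.end) // 2
        if mid < cen_s:
            p.append(seg)
        elif mid >= cen_e:
            q.append(seg)
        else:  # midpoint inside the centromere: nearer arm
            (p if mid - cen_s < cen_e - mid else q).append(seg)
    return [p, q]


def compute_lst(
    profile: SegmentProfile,
    build: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> int:
    """Large-scale state transitions.

    Per arm, after absorbing sub-``lst_smooth_below`` fragments, count
    junctions whose two flanking segments are both >= ``lst_min_flank``,
    differ in (total, minor) state, and are separated by at most
    ``lst_max_gap``.
    """
    count = 0
    for chrom in _included_chroms(profile, params):
        if chrom not in build:
            continue
        segs = profile.segments_of(chrom)
        if len(segs) < 2:
            continue
        c = build[chrom]
        for arm in _arm_segments(segs, c.centromere, c.length):
            sm = smooth_segments(arm, params.lst_smooth_below)
            for a, b in zip(sm, sm[1:]):
                if (
                    a.length >= params.lst_min_flank
                    and b.length >= params.lst_min_flank
                    and a.state() != b.state()
                    and b.start - a.end <= params.lst_max_gap
                ):
                    count += 1
    return count


# ---------------------------------------------------------------------------
# HRD-LOH
# ---------------------------------------------------------------------------

def compute_hrd_loh(
    profile: SegmentProfile,
    build: GenomeBuild | None = None,
    params: ScarParams = ScarParams(),
) -> tuple[int, int]:
    """Count LOH tracts larger than ``hrd_loh_min_size`` (strict) that do
    not span the entire covered extent of their chromosome.

    ``hrd_loh_mode="cnloh"`` restricts to copy-neutral LOH, matching the
    definition used here; ``"any_loh"`` counts every LOH tract.  Touching
    equal-state segments are merged first so tract lengths do not depend
    on how the segmentation was split.  Returns ``(count, n_missing_minor)``.
    """
    from .genome import normalize_profile

    _require_minor(profile, "HRD-LOH")
    profile = normalize_profile(profile)
    count = 0
    missing = 0
    for chrom in _included_chroms(profile, params):
        segs = profile.segments_of(chrom)
        if not segs:
            continue
        ext = profile.covered_extent(chrom)
        assert ext is not None
        cov_start, cov_end = ext
        for seg in segs:
            if seg.minor_cn is None:
                missing += 1
                continue
            loh = seg.is_cnloh if params.hrd_loh_mode == "cnloh" else seg.is_loh
            if not loh:
                continue
            if seg.length <= params.hrd_loh_min_size:
                continue
            if seg.start <= cov_start and seg.end >= cov_end:
                continue  # whole-chromosome LOH does not count
            count += 1
    return count, missing


# ---------------------------------------------------------------------------
# sample and cohort level
# ---------------------------------------------------------------------------

def score_sample(
    profile: SegmentProfile,
    build: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> ScarScores:
    """Bundle GII, TAI, LST, HRD-LOH, HRD-sum and the fixed-threshold flags."""
    gii = compute_gii(profile, build, params)
    ploidy, ploidy_class = estimate_ploidy(profile, params)
    tai, miss_tai = compute_tai(profile, build, params)
    lst = compute_lst(profile, build, params)
    hrd_loh, miss_loh = compute_hrd_loh(profile, build, params)
    hrd_sum = tai + lst + hrd_loh
    lst_cut = (
        params.lst_high_diploid_above
        if ploidy_class == "diploid"
        else params.lst_high_polyploid_above
    )
    return ScarScores(
        sample=profile.sample,
        gii=gii,
        tai=tai,
        lst=lst,
        hrd_loh=hrd_loh,
        hrd_sum=hrd_sum,
        ploidy=ploidy,
        ploidy_class=ploidy_class,
        lst_high=lst > lst_cut,
        hrd_loh_high=hrd_loh >= params.hrd_loh_high_at_least,
        hrd_sum_high=hrd_sum >= params.hrd_sum_high_at_least,
        n_missing_minor=max(miss_tai, miss_loh),
        params={"hrd_loh_mode": params.hrd_loh_mode},
    )


def dichotomize_cohort(scores: Sequence[ScarScores]) -> list[ScarScores]:
    """Label GII and TAI high/low against the cohort median (strict >).

    Ties at the median are "low".  Returns the updated scores.
    """
    if len(scores) < 2:
        raise ValueError("dichotomization needs at least 2 samples")
    gii_med = float(np.median([s.gii for s in scores]))
    tai_med = float(np.median([s.tai for s in scores]))
    for s in scores:
        s.gii_high = s.gii > gii_med
        s.tai_high = s.tai > tai_med
    return list(scores)


def scores_to_frame(scores: Sequence[ScarScores]) -> pd.DataFrame:
    cols = [
        "sample", "gii", "tai", "lst", "hrd_loh", "hrd_sum", "ploidy",
        "ploidy_class", "lst_high", "hrd_loh_high", "hrd_sum_high",
        "gii_high", "tai_high", "n_missing_minor",
    ]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in scores])


# ---------------------------------------------------------------------------
# cohort recurrence
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceTrack:
    """Binned per-cohort alteration frequencies with recurrent flags.

    Gains/losses are recurrent when carried by strictly more than half of
    the samples; cnLOH when carried by at least a quarter.
    """

    bins: pd.DataFrame  # chrom,start,end,gain_frac,loss_frac,cnloh_frac,+flags
    n_samples: int
    bin_size: int

    def recurrent(self, kind: str) -> pd.DataFrame:
        return self.bins[self.bins[f"recurrent_{kind}"]]


def cohort_recurrence(
    profiles: Sequence[SegmentProfile],
    build: GenomeBuild,
    bin_size: int = 1_000_000,
    params: ScarParams = ScarParams(),
    gain_loss_frac_above: float = 0.50,
    cnloh_frac_at_least: float = 0.25,
) -> RecurrenceTrack:
    """Per-bin fraction of samples with gain / loss / cnLOH, with flags."""
    if not profiles:
        raise ValueError("no profiles")
    n = len(profiles)
    rows = []
    chroms = build.names
    if not params.include_sex_chromosomes:
        chroms = [c for c in chroms if c not in SEX_CHROMOSOMES]
    for chrom in chroms:
        length = build[chrom].length
        edges = np.arange(0, length + bin_size, bin_size)
        n_bins = len(edges) - 1
        gain = np.zeros(n_bins)
        loss = np.zeros(n_bins)
        cnloh = np.zeros(n_bins)
        for prof in profiles:
            g = np.zeros(n_bins, dtype=bool)
            l = np.zeros(n_bins, dtype=bool)
            c = np.zeros(n_bins, dtype=bool)
            for seg in prof.segments_of(chrom):
                lo = int(seg.start // bin_size)
                hi = int(min((seg.end - 1) // bin_size, n_bins - 1))
                if seg.total_cn > params.baseline_cn + CN_TOL:
                    g[lo : hi + 1] = True
                elif seg.total_cn < params.baseline_cn - CN_TOL:
                    l[lo : hi + 1] = True
                if seg.is_cnloh:
                    c[lo : hi + 1] = True
            gain += g
            loss += l
            cnloh += c
        for i in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(edges[i]),
                    "end": int(min(edges[i + 1], length)),
                    "gain_frac": gain[i] / n,
                    "loss_frac": loss[i] / n,
                    "cnloh_frac": cnloh[i] / n,
                }
            )
    bins = pd.DataFrame(rows)
    bins["recurrent_gain"] = bins["gain_frac"] > gain_loss_frac_above
    bins["recurrent_loss"] = bins["loss_frac"] > gain_loss_frac_above
    bins["recurrent_cnloh"] = bins["cnloh_frac"] >= cnloh_frac_at_least
    return RecurrenceTrack(bins=bins, n_samples=n, bin_size=bin_size)
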