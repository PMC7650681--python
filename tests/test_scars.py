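"""Scar scores: GII, ploidy, TAI, LST, HRD-LOH, thresholds, recurrence."""

from __future__ import annotations

import statistics

import numpy as np
import pytest

from ibcscars import (
    ScarParams,
    ScarScores,
    Segment,
    cohort_recurrence,
    compute_gii,
    compute_hrd_loh,
    compute_lst,
    compute_tai,
    dichotomize_cohort,
    estimate_ploidy,
    make_toy_build,
    profile_from_segments,
    score_sample,
    simulate_profile,
)

MB = 1_000_000


def prof(*segs, sample="S1"):
    return profile_from_segments(sample, list(segs))


# ---------------------------------------------------------------------------
# GII and ploidy
# ---------------------------------------------------------------------------

def test_gii_zero_on_baseline(toy_build, quiet_profile):
    assert compute_gii(quiet_profile, toy_build) == 0.0


def test_gii_is_altered_fraction_of_covered_genome(toy_build):
    p = prof(
        Segment("chr1", 0, 30 * MB, 3.0, 1.0),
        Segment("chr1", 30 * MB, 100 * MB, 2.0, 1.0),
    )
    assert compute_gii(p, toy_build) == pytest.approx(0.3)


def test_gii_ignores_cnloh(toy_build):
    p = prof(
        Segment("chr1", 0, 50 * MB, 2.0, 0.0),  # copy-neutral: not a CNA
        Segment("chr1", 50 * MB, 100 * MB, 2.0, 1.0),
    )
    assert compute_gii(p, toy_build) == 0.0


def test_gii_empty_profile_errors(toy_build):
    with pytest.raises(ValueError, match="empty"):
        compute_gii(profile_from_segments("S1", []), toy_build)


def test_gii_one_iff_all_altered(toy_build):
    p = prof(Segment("chr1", 0, 100 * MB, 4.0, 2.0))
    assert compute_gii(p, toy_build) == 1.0


@pytest.mark.parametrize(
    "cns,expected_ploidy,expected_class",
    [
        ([2.0, 2.0], 2.0, "diploid"),
        ([4.0, 4.0], 4.0, "polyploid"),
        ([2.0, 3.0], 2.5, "diploid"),  # boundary: strictly above 2.5
    ],
)
def test_estimate_ploidy(cns, expected_ploidy, expected_class):
    p = prof(
        Segment("chr1", 0, 50 * MB, cns[0], 1.0),
        Segment("chr1", 50 * MB, 100 * MB, cns[1], 1.0),
    )
    ploidy, cls = estimate_ploidy(p)
    assert ploidy == pytest.approx(expected_ploidy)
    assert cls == expected_class


# ---------------------------------------------------------------------------
# TAI
# ---------------------------------------------------------------------------

def brute_force_tai(profile, build, telomere_tol=1_000, min_size=0):
    """Independent enumeration of the TAI criteria, one arm at a time."""
    total = 0
    for chrom in profile.chromosomes:
        if chrom not in build:
            continue
        segs = profile.segments_of(chrom)
        if not segs:
            continue
        lo = min(s.start for s in segs)
        hi = max(s.end for s in segs)
        cen = build[chrom].centromere
        p_found = q_found = False
        for s in segs:
            if s.minor_cn is None or not s.allelic_imbalance:
                continue
            if s.length < min_size:
                continue
            if cen and s.start < cen[1] and s.end > cen[0]:
                continue
            if s.start <= lo + telomere_tol:
                p_found = True
            if s.end >= hi - telomere_tol:
                q_found = True
        total += int(p_found) + int(q_found)
    return total


def test_tai_quiet_profile_is_zero(toy_build, quiet_profile):
    assert compute_tai(quiet_profile, toy_build)[0] == 0


def test_tai_requires_allele_specific_data(toy_build):
    p = prof(Segment("chr1", 0, 100 * MB, 2.0, None))
    with pytest.raises(ValueError, match="allele-specific"):
        compute_tai(p, toy_build)


def test_tai_centromere_crossing_segment_does_not_count(toy_build):
    # AI over a whole chromosome crosses the centromere: contributes 0
    p = prof(Segment("chr1", 0, 100 * MB, 3.0, 1.0))
    assert compute_tai(p, toy_build)[0] == 0
    assert brute_force_tai(p, toy_build) == 0


def test_tai_planted_terminal_segments_vs_brute_force(big_build):
    """7 terminal AI segments + 2 centromere-spanning AI segments -> 7."""
    segs = []
    terminal = 0
    for i, c in enumerate(big_build.chromosomes):
        if i < 4:  # both ends AI on 3 chroms, p-end only on the 4th
            segs.append(Segment(c.name, 0, 8 * MB, 3.0, 1.0))
            terminal += 1
            if i < 3:
                segs.append(Segment(c.name, c.length - 8 * MB, c.length, 3.0, 1.0))
                terminal += 1
            segs.append(Segment(c.name, 8 * MB, c.length - 8 * MB, 2.0, 1.0))
        elif i < 6:  # centromere-spanning AI: disqualified
            segs.append(Segment(c.name, 30 * MB, 70 * MB, 3.0, 1.0))
            segs.append(Segment(c.name, 0, 30 * MB, 2.0, 1.0))
            segs.append(Segment(c.name, 70 * MB, c.length, 2.0, 1.0))
        else:
            segs.append(Segment(c.name, 0, c.length, 2.0, 1.0))
    p = profile_from_segments("S1", segs)
    assert terminal == 7
    got = compute_tai(p, big_build)[0]
    assert got == 7 == brute_force_tai(p, big_build)


# ---------------------------------------------------------------------------
# LST
# ---------------------------------------------------------------------------

def test_lst_counts_qualifying_junction(toy_build):
    p = prof(
        Segment("chr1", 60 * MB, 72 * MB, 2.0, 1.0),
        Segment("chr1", 72 * MB, 84 * MB, 3.0, 1.0),
    )
    assert compute_lst(p, toy_build) == 1


def test_lst_flanks_below_10mb_do_not_count(toy_build):
    p = prof(
        Segment("chr1", 60 * MB, 68 * MB, 2.0, 1.0),
        Segment("chr1", 68 * MB, 76 * MB, 3.0, 1.0),
    )
    assert compute_lst(p, toy_build) == 0


def test_lst_gap_above_3mb_does_not_count(toy_build):
    p = prof(
        Segment("chr1", 55 * MB, 67 * MB, 2.0, 1.0),
        Segment("chr1", 71 * MB, 83 * MB, 3.0, 1.0),  # 4 Mb gap
    )
    assert compute_lst(p, toy_build) == 0


def test_lst_unchanged_by_sub_smoothing_spacer(toy_build):
    """A <3 Mb spacer inside a >=10 Mb flank is absorbed before counting."""
    base = prof(
        Segment("chr1", 52 * MB, 70 * MB, 2.0, 1.0),
        Segment("chr1", 70 * MB, 85 * MB, 3.0, 1.0),
    )
    spaced = prof(
        Segment("chr1", 52 * MB, 60 * MB, 2.0, 1.0),
        Segment("chr1", 60 * MB, 62 * MB, 5.0, 1.0),  # spacer
        Segment("chr1", 62 * MB, 70 * MB, 2.0, 1.0),
        Segment("chr1", 70 * MB, 85 * MB, 3.0, 1.0),
    )
    assert compute_lst(base, toy_build) == compute_lst(spaced, toy_build) == 1


def test_lst_does_not_count_across_centromere(toy_build):
    # junction at the centromere: the two segments live on different arms
    p = prof(
        Segment("chr1", 30 * MB, 49 * MB, 2.0, 1.0),
        Segment("chr1", 51 * MB, 70 * MB, 3.0, 1.0),
    )
    assert compute_lst(p, toy_build) == 0


# ---------------------------------------------------------------------------
# HRD-LOH
# ---------------------------------------------------------------------------

def test_hrd_loh_counts_long_subchromosomal_tract(toy_build):
    p = prof(
        Segment("chr1", 10 * MB, 30 * MB, 2.0, 0.0),  # 20 Mb cnLOH
        Segment("chr1", 30 * MB, 100 * MB, 2.0, 1.0),
    )
    assert compute_hrd_loh(p, toy_build)[0] == 1


def test_hrd_loh_14mb_tract_below_threshold(toy_build):
    p = prof(
        Segment("chr1", 10 * MB, 24 * MB, 2.0, 0.0),
        Segment("chr1", 24 * MB, 100 * MB, 2.0, 1.0),
    )
    assert compute_hrd_loh(p, toy_build)[0] == 0


def test_hrd_loh_whole_chromosome_excluded(toy_build):
    p = prof(Segment("chr1", 0, 100 * MB, 2.0, 0.0))
    assert compute_hrd_loh(p, toy_build)[0] == 0


def test_hrd_loh_any_loh_mode_counts_deletion_loh(toy_build):
    p = prof(
        Segment("chr1", 10 * MB, 30 * MB, 1.0, 0.0),  # deletion LOH
        Segment("chr1", 30 * MB, 100 * MB, 2.0, 1.0),
    )
    assert compute_hrd_loh(p, toy_build)[0] == 0
    any_loh = ScarParams(hrd_loh_mode="any_loh")
    assert compute_hrd_loh(p, toy_build, any_loh)[0] == 1


# ---------------------------------------------------------------------------
# sample-level thresholds
# ---------------------------------------------------------------------------

def make_scores(tai=0, lst=0, hrd_loh=0, ploidy_class="diploid"):
    params = ScarParams()
    cut = (
        params.lst_high_diploid_above
        if ploidy_class == "diploid"
        else params.lst_high_polyploid_above
    )
    return ScarScores(
        sample="S",
        gii=0.0,
        tai=tai,
        lst=lst,
        hrd_loh=hrd_loh,
        hrd_sum=tai + lst + hrd_loh,
        ploidy=2.0 if ploidy_class == "diploid" else 4.0,
        ploidy_class=ploidy_class,
        lst_high=lst > cut,
        hrd_loh_high=hrd_loh >= params.hrd_loh_high_at_least,
        hrd_sum_high=(tai + lst + hrd_loh) >= params.hrd_sum_high_at_least,
    )


def test_quiet_sample_all_flags_low(toy_build, quiet_profile):
    s = score_sample(quiet_profile, toy_build)
    assert (s.tai, s.lst, s.hrd_loh, s.hrd_sum) == (0, 0, 0, 0)
    assert not (s.lst_high or s.hrd_loh_high or s.hrd_sum_high)


def test_hrd_sum_42_is_high():
    s = make_scores(tai=12, lst=20, hrd_loh=10)
    assert s.hrd_sum == 42 and s.hrd_sum_high


def test_lst_16_high_depends_on_ploidy_class():
    assert make_scores(lst=16).lst_high
    assert not make_scores(lst=16, ploidy_class="polyploid").lst_high
    assert make_scores(lst=21, ploidy_class="polyploid").lst_high


def test_hrd_loh_10_is_high():
    assert make_scores(hrd_loh=10).hrd_loh_high
    assert not make_scores(hrd_loh=9).hrd_loh_high


# ---------------------------------------------------------------------------
# cohort dichotomization
# ---------------------------------------------------------------------------

def test_dichotomize_strictly_above_median():
    scores = [make_scores(tai=t) for t in (10, 19, 20, 25)]
    dichotomize_cohort(scores)
    # median 19.5: 20 and 25 high, 10 and 19 low
    assert [s.tai_high for s in scores] == [False, False, True, True]


def test_dichotomize_all_equal_none_high():
    scores = [make_scores(tai=5) for _ in range(4)]
    dichotomize_cohort(scores)
    assert not any(s.tai_high for s in scores)


def test_dichotomize_single_sample_errors():
    with pytest.raises(ValueError, match="2 samples"):
        dichotomize_cohort([make_scores()])


def test_dichotomize_matches_brute_force_median():
    rng = np.random.default_rng(0)
    tais = rng.integers(0, 40, size=25)
    scores = [make_scores(tai=int(t)) for t in tais]
    dichotomize_cohort(scores)
    med = statistics.median(int(t) for t in tais)
    assert [s.tai_high for s in scores] == [int(t) > med for t in tais]


# ---------------------------------------------------------------------------
# recurrence
# ---------------------------------------------------------------------------

def test_cohort_recurrence_thresholds(toy_build):
    def one(sample, cn, minor):
        return prof(
            Segment("chr1", 0, 10 * MB, cn, minor),
            Segment("chr1", 10 * MB, 100 * MB, 2.0, 1.0),
            sample=sample,
        )

    # 3/4 gain -> recurrent; 2/4 loss -> NOT (strict >); 1/4 cnLOH -> recurrent (>=)
    gain_profiles = [one(f"G{i}", 3.0, 1.0) for i in range(3)] + [
        one("G3", 2.0, 1.0)
    ]
    track = cohort_recurrence(gain_profiles, toy_build, bin_size=10 * MB)
    first = track.bins.iloc[0]
    assert first["gain_frac"] == 0.75 and first["recurrent_gain"]

    loss_profiles = [one(f"L{i}", 1.0, 0.0) for i in range(2)] + [
        one(f"L{i+2}", 2.0, 1.0) for i in range(2)
    ]
    track = cohort_recurrence(loss_profiles, toy_build, bin_size=10 * MB)
    first = track.bins.iloc[0]
    assert first["loss_frac"] == 0.50 and not first["recurrent_loss"]

    cnloh_profiles = [one("C0", 2.0, 0.0)] + [one(f"C{i+1}", 2.0, 1.0) for i in range(3)]
    track = cohort_recurrence(cnloh_profiles, toy_build, bin_size=10 * MB)
    first = track.bins.iloc[0]
    assert first["cnloh_frac"] == 0.25 and first["recurrent_cnloh"]


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

def test_scores_invariant_under_coordinate_translation():
    """Shifting a whole chromosome (profile and build together) changes nothing."""
    from ibcscars import Chromosome, GenomeBuild

    shift = 7 * MB
    base_build = make_toy_build(n_chrom=1)
    shifted_build = GenomeBuild(
        name="shifted",
        chromosomes=(
            Chromosome(
                "chr1",
                base_build["chr1"].length + shift,
                tuple(x + shift for x in base_build["chr1"].centromere),
            ),
        ),
    )
    segs = [
        Segment("chr1", 0, 8 * MB, 3.0, 1.0),
        Segment("chr1", 8 * MB, 60 * MB, 2.0, 1.0),
        Segment("chr1", 60 * MB, 80 * MB, 2.0, 0.0),
        Segment("chr1", 80 * MB, 100 * MB, 2.0, 1.0),
    ]
    p0 = profile_from_segments("S1", segs)
    p1 = profile_from_segments(
        "S1",
        [Segment(s.chrom, s.start + shift, s.end + shift, s.total_cn, s.minor_cn) for s in segs],
    )
    s0 = score_sample(p0, base_build)
    s1 = score_sample(p1, shifted_build)
    assert (s0.gii, s0.tai, s0.lst, s0.hrd_loh) == (s1.gii, s1.tai, s1.lst, s1.hrd_loh)


def test_hrd_sum_additivity_on_simulated_profiles(big_build):
    for seed in range(5):
        p, _ = simulate_profile(big_build, n_tai=3, n_lst=2, n_loh=1, seed=seed)
        s = score_sample(p, big_build)
        assert s.hrd_sum == s.tai + s.lst + s.hrd_loh
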