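"""Genome geometry and allele-specific copy-number segment containers.

All coordinates are internally 0-based, half-open.  The SEG dialect
(1-based, end-inclusive, the convention of most array-segmentation
exports) is converted on read and restored on write.

Copy numbers are stored as floats: array segmentation emits non-integer
estimates, and every predicate that compares copy-number states does so
through a small tolerance (:data:`CN_TOL`).
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

#: tolerance used everywhere two copy-number values are compared
CN_TOL = 1e-6

#: copy number of the diploid reference; cnLOH is defined against it
BASELINE_CN = 2

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


# ---------------------------------------------------------------------------
# genome build
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    #: centromere interval [start, end) in bp; None if unknown
    centromere: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.centromere is not None:
            s, e = self.centromere
            if not (0 <= s < e <= self.length):
                raise ValueError(
                    f"chromosome {self.name}: centromere [{s},{e}) must be a "
                    f"non-empty interval inside [0,{self.length})"
                )


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths plus centromere intervals.

    The centromere interval splits each chromosome into a p arm
    ``[0, cen_start)`` and a q arm ``[cen_end, length)``; every score that
    needs arm geometry (TAI, LST) works against this frame.
    """

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        object.__setattr__(
            self, "_by_name", {c.name: c for c in self.chromosomes}
        )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._by_name  # type: ignore[attr-defined]

    def __getitem__(self, chrom: str) -> Chromosome:
        return self._by_name[chrom]  # type: ignore[attr-defined]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def arms(self, chrom: str) -> list[tuple[str, int, int]]:
        """Arm intervals ``(arm, start, end)``; one pseudo-arm if no centromere."""
        c = self[chrom]
        if c.centromere is None:
            return [("", 0, c.length)]
        s, e = c.centromere
        return [("p", 0, s), ("q", e, c.length)]


def read_cytoband(path: str | Path) -> GenomeBuild:
    """Build a :class:`GenomeBuild` from a UCSC-style cytoBand file.

    Expects tab-separated ``chrom  start  end  band  stain`` rows,
    optionally gzip-compressed.  Each chromosome's centromere is the
    bounding interval of its ``acen`` bands and its length the maximum
    band end.  Chromosomes without an ``acen`` band get ``centromere=None``
    (callers may supply centromeres explicitly).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    lengths: dict[str, int] = {}
    acen: dict[str, list[int]] = {}
    order: list[str] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
            chrom, start, end, _band, stain = parts[:5]
            start_i, end_i = int(start), int(end)
            if chrom not in lengths:
                order.append(chrom)
                lengths[chrom] = 0
            lengths[chrom] = max(lengths[chrom], end_i)
            if stain == "acen":
                acen.setdefault(chrom, [end_i, start_i])
                acen[chrom][0] = min(acen[chrom][0], start_i)
                acen[chrom][1] = max(acen[chrom][1], end_i)
    if not lengths:
        raise ValueError(f"{path}: no bands")
    chroms = tuple(
        Chromosome(
            name=c,
            length=lengths[c],
            centromere=tuple(acen[c]) if c in acen else None,
        )
        for c in order
    )
    return GenomeBuild(name=path.stem, chromosomes=chroms)


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")
        if self.minor_cn is not None:
            if self.minor_cn < 0:
                raise ValueError("minor_cn must be >= 0")
            if self.minor_cn > self.total_cn / 2 + CN_TOL:
                raise ValueError(
                    f"{self.chrom}:{self.start}-{self.end}: minor_cn "
                    f"{self.minor_cn} exceeds total_cn/2 ({self.total_cn / 2})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def major_cn(self) -> Optional[float]:
        if self.minor_cn is None:
            return None
        return self.total_cn - self.minor_cn

    @property
    def allelic_imbalance(self) -> Optional[bool]:
        """True if the two parental alleles have unequal copy counts.

        None ("unknown") when no minor-allele call is present.
        """
        if self.minor_cn is None:
            return None
        return abs(self.total_cn - 2 * self.minor_cn) > CN_TOL

    @property
    def is_loh(self) -> Optional[bool]:
        if self.minor_cn is None:
            return None
        return self.minor_cn <= CN_TOL and self.total_cn >= 1 - CN_TOL

    @property
    def is_cnloh(self) -> Optional[bool]:
        """Copy-neutral LOH: minor allele lost, total at the diploid baseline."""
        loh = self.is_loh
        if loh is None:
            return None
        return loh and abs(self.total_cn - BASELINE_CN) <= CN_TOL

    def state(self) -> tuple[float, Optional[float]]:
        """Rounded (total, minor) state used for equality of adjacent segments."""
        m = None if self.minor_cn is None else round(self.minor_cn, 6)
        return (round(self.total_cn, 6), m)


@dataclass
class SegmentProfile:
    """Per-sample ordered, non-overlapping segments grouped by chromosome."""

    sample: str
    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, segs in self.segments.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"sample {self.sample}: overlapping segments "
                        f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                    )
            self.segments[chrom] = segs

    @property
    def chromosomes(self) -> list[str]:
        return list(self.segments)

    def segments_of(self, chrom: str) -> list[Segment]:
        return self.segments.get(chrom, [])

    def __iter__(self) -> Iterator[Segment]:
        for segs in self.segments.values():
            yield from segs

    def covered_extent(self, chrom: str) -> Optional[tuple[int, int]]:
        """[min start, max end) actually covered on *chrom*, or None."""
        segs = self.segments_of(chrom)
        if not segs:
            return None
        return segs[0].start, max(s.end for s in segs)

    def covered_length(self, chroms: Optional[Iterable[str]] = None) -> int:
        names = list(chroms) if chroms is not None else self.chromosomes
        return sum(s.length for c in names for s in self.segments_of(c))

    def has_minor_cn(self) -> bool:
        return any(s.minor_cn is not None for s in self)

    def summary(self) -> dict:
        return {
            "sample": self.sample,
            "n_chromosomes": len(self.segments),
            "n_segments": sum(len(v) for v in self.segments.values()),
            "covered_bp": self.covered_length(),
        }


def profile_from_segments(sample: str, segments: Iterable[Segment]) -> SegmentProfile:
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    return SegmentProfile(sample=sample, segments=by_chrom)


# ---------------------------------------------------------------------------
# segment I/O
# ---------------------------------------------------------------------------

DIALECTS = ("seg-1-based-inclusive", "bed-0-based-half-open")
_REQUIRED_COLS = ("sample", "chrom", "start", "end", "total_cn")


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")


def read_segments(path: str | Path, dialect: str = "seg-1-based-inclusive") -> list[SegmentProfile]:
    """Read SEG-like TSV into per-sample profiles.

    Required columns: ``sample chrom start end total_cn``; ``minor_cn`` is
    optional (empty cells → no allele-specific call for that segment).
    Coordinates are normalized to 0-based half-open.
    """
    _check_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    profiles: list[SegmentProfile] = []
    offset = 1 if dialect == "seg-1-based-inclusive" else 0
    for col in ("start", "end", "total_cn") + (("minor_cn",) if "minor_cn" in df else ()):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
    for sample, sub in df.groupby("sample", sort=False):
        segs = []
        for row in sub.itertuples(index=False):
            minor = getattr(row, "minor_cn", None)
            if minor is not None and pd.isna(minor):
                minor = None
            segs.append(
                Segment(
                    chrom=row.chrom,
                    start=int(row.start) - offset,
                    end=int(row.end) - offset + (1 if offset else 0),
                    total_cn=float(row.total_cn),
                    minor_cn=None if minor is None else float(minor),
                )
            )
        profiles.append(profile_from_segments(str(sample), segs))
    return profiles


def write_segments(
    profiles: Sequence[SegmentProfile],
    path: str | Path,
    dialect: str = "seg-1-based-inclusive",
    summary_path: str | Path | None = None,
) -> None:
    """Write profiles as SEG-like TSV; optional JSON profile summary."""
    _check_dialect(dialect)
    offset = 1 if dialect == "seg-1-based-inclusive" else 0
    rows = []
    for prof in profiles:
        for seg in prof:
            rows.append(
                {
                    "sample": prof.sample,
                    "chrom": seg.chrom,
                    "start": seg.start + offset,
                    "end": seg.end + offset - (1 if offset else 0),
                    "total_cn": f"{seg.total_cn:.6g}",
                    "minor_cn": "" if seg.minor_cn is None else f"{seg.minor_cn:.6g}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump([p.summary() for p in profiles], fh, indent=1)


def normalize_profile(profile: SegmentProfile, merge_tol: float = 0.0) -> SegmentProfile:
    """Merge adjacent touching segments whose CN states agree within *merge_tol*.

    Idempotent; with the default ``merge_tol=0`` only exactly equal states
    merge, so every score is invariant under arbitrary splitting of
    segments into touching equal-state pieces.
    """
    out: dict[str, list[Segment]] = {}
    for chrom, segs in profile.segments.items():
        merged: list[Segment] = []
        for seg in segs:
            if merged:
                prev = merged[-1]
                same_minor = (prev.minor_cn is None) == (seg.minor_cn is None) and (
                    prev.minor_cn is None
                    or abs(prev.minor_cn - seg.minor_cn) <= merge_tol + CN_TOL
                )
                if (
                    prev.end == seg.start
                    and abs(prev.total_cn - seg.total_cn) <= merge_tol + CN_TOL
                    and same_minor
                ):
                    merged[-1] = replace(prev, end=seg.end)
                    continue
            merged.append(seg)
        out[chrom] = merged
    return SegmentProfile(sample=profile.sample, segments=out)
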