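"""Genomic interval data model and operations.

Coordinates are 0-based half-open throughout (BED convention); a narrowPeak
summit is a 0-based offset from the interval start.  The module provides the
interval primitives every downstream analysis builds on: BED/narrowPeak I/O,
summit windows, exact intersection, uniform length-preserving shuffling (the
permutation null), and two-nearest-gene assignment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "BedParseError",
    "GenomeBuild",
    "Interval",
    "PeakSet",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "summit_position",
    "summit_window",
    "intersect",
    "shuffle",
    "two_nearest_genes",
]

Dialect = Literal["bed3", "bed6", "narrowPeak"]


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class BedParseError(ValueError):
    """A BED-family file could not be parsed; message names the line."""


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with lengths in bp."""

    name: str
    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        if not self.chroms or any(n <= 0 for _, n in self.chroms):
            raise ValidationError("chromosome lengths must be positive and non-empty")
        object.__setattr__(self, "chroms", tuple((c, int(n)) for c, n in self.chroms))

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chroms)

    def length(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} not in genome {self.name!r}")

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chroms)


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval, optionally carrying a summit offset."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise ValidationError(
                f"summit offset {self.summit} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return min(self.end, other.end) - max(self.start, other.start)


def summit_position(interval: Interval) -> int:
    """Absolute summit coordinate; midpoint when no summit was recorded."""
    if interval.summit is not None:
        return interval.start + interval.summit
    return (interval.start + interval.end) // 2


class PeakSet:
    """An immutable, sorted collection of distinct intervals."""

    def __init__(self, intervals: Iterable[Interval], label: str = "") -> None:
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        for a, b in zip(ivs, ivs[1:]):
            if a == b:
                raise ValidationError(f"duplicate interval {a}")
        self.label = label
        self.intervals: tuple[Interval, ...] = tuple(ivs)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    def validate_against(self, genome: GenomeBuild) -> None:
        for iv in self.intervals:
            if iv.end > genome.length(iv.chrom):
                raise ValidationError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome bounds"
                )

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, original indices), sorted by start."""
        if self._by_chrom is None:
            out: dict[str, list[list[int]]] = {}
            for i, iv in enumerate(self.intervals):
                out.setdefault(iv.chrom, [[], [], []])
                out[iv.chrom][0].append(iv.start)
                out[iv.chrom][1].append(iv.end)
                out[iv.chrom][2].append(i)
            self._by_chrom = {
                c: tuple(np.asarray(v, dtype=np.int64) for v in cols)  # type: ignore[misc]
                for c, cols in out.items()
            }
        return self._by_chrom


# ---------------------------------------------------------------------------
# BED-family I/O

_NP_COLS = 10


def _parse_line(fields: list[str], dialect: Dialect, lineno: int) -> Interval:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise BedParseError(f"line {lineno}: malformed coordinates: {exc}") from None
    if start >= end:
        raise BedParseError(f"line {lineno}: start {start} >= end {end}")
    name = score = summit = None
    if dialect in ("bed6", "narrowPeak"):
        try:
            name = fields[3] if fields[3] != "." else None
            score = float(fields[4]) if fields[4] != "." else None
        except IndexError:
            raise BedParseError(f"line {lineno}: too few columns for {dialect}") from None
    if dialect == "narrowPeak":
        if len(fields) < _NP_COLS:
            raise BedParseError(f"line {lineno}: narrowPeak needs {_NP_COLS} columns")
        s = int(fields[9])
        summit = None if s == -1 else s
    try:
        return Interval(chrom, start, end, name=name, score=score, summit=summit)
    except ValidationError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from None


def read_bed(path, dialect: Dialect = "bed3", label: str = "") -> PeakSet:
    """Read a BED3 / BED6 / ENCODE narrowPeak file into a sorted PeakSet.

    A narrowPeak column-10 value of -1 maps to "summit absent".  Coordinates
    are validated against no genome here; callers holding a
    :class:`GenomeBuild` use :meth:`PeakSet.validate_against`.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_line(line.split("\t"), dialect, lineno))
    return PeakSet(intervals, label=label or str(path))


def write_bed(peakset: PeakSet, path, dialect: Dialect = "bed3") -> None:
    """Write a PeakSet; fields the dialect cannot carry are dropped."""
    with open(path, "w") as fh:
        for iv in peakset:
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if dialect in ("bed6", "narrowPeak"):
                row += [
                    iv.name if iv.name is not None else ".",
                    _fmt_score(iv.score),
                    ".",
                ]
            if dialect == "narrowPeak":
                row += ["0", "-1", "-1", str(iv.summit if iv.summit is not None else -1)]
            fh.write("\t".join(row) + "\n")


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_chrom_sizes(path, name: str = "custom") -> GenomeBuild:
    """Two-column TSV (chrom, length) -> GenomeBuild."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeBuild(name, tuple(zip(df["chrom"].astype(str), df["length"].astype(int))))


# ---------------------------------------------------------------------------
# Summit windows

def summit_window(interval: Interval, k: int, genome: GenomeBuild | None = None) -> Interval:
    """The +/- k bp window around the summit, clipped to chromosome bounds.

    Returns ``[summit-k, summit+k+1)``; width is ``2k+1`` away from edges.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    pos = summit_position(interval)
    start = max(pos - k, 0)
    end = pos + k + 1
    if genome is not None:
        end = min(end, genome.length(interval.chrom))
        start = min(start, end - 1)
    return Interval(
        interval.chrom, start, end, name=interval.name, score=interval.score,
        summit=pos - start,
    )


# ---------------------------------------------------------------------------
# Intersection

def intersect(
    set_a: PeakSet, set_b: PeakSet, min_overlap_bp: int = 1
) -> list[tuple[int, int, int]]:
    """All pairs (index_a, index_b, overlap_bp) overlapping >= min_overlap_bp."""
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    bmap = set_b.by_chrom()
    out: list[tuple[int, int, int]] = []
    for i, iv in enumerate(set_a):
        grp = bmap.get(iv.chrom)
        if grp is None:
            continue
        starts, ends, idx = grp
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        for j in np.nonzero(ov >= min_overlap_bp)[0]:
            out.append((i, int(idx[j]), int(ov[j])))
    return out


class OverlapCounter:
    """Fast 'does an interval hit set B' counter over merged B intervals.

    Used by the permutation null, where B is fixed and thousands of shuffled
    A placements must be scored.  Supports the any-overlap criterion only
    (min_overlap_bp = 1); the first merged interval ending past the query
    start then decides, which a single binary search finds.
    """

    def __init__(self, set_b: PeakSet, genome: GenomeBuild, min_overlap_bp: int = 1):
        if min_overlap_bp != 1:
            raise ValidationError("OverlapCounter supports min_overlap_bp = 1 only")
        self.min_overlap = min_overlap_bp
        self.chrom_names = [c for c, _ in genome.chroms]
        self._merged: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        bmap = set_b.by_chrom()
        for ci, cname in enumerate(self.chrom_names):
            if cname not in bmap:
                continue
            starts, ends, _ = bmap[cname]
            order = np.argsort(starts, kind="stable")
            ms, me = [], []
            for s, e in zip(starts[order], ends[order]):
                if ms and s < me[-1]:  # touching intervals stay separate windows
                    me[-1] = max(me[-1], e)
                else:
                    ms.append(int(s))
                    me.append(int(e))
            self._merged[ci] = (np.asarray(ms), np.asarray(me))

    def count_hits(self, chrom_idx: np.ndarray, starts: np.ndarray, lengths: np.ndarray) -> int:
        """Number of (chrom_idx, start, length) intervals overlapping B by
        >= min_overlap_bp."""
        d = self.min_overlap
        total = 0
        for ci, (ms, me) in self._merged.items():
            sel = chrom_idx == ci
            if not sel.any():
                continue
            s = starts[sel]
            e = s + lengths[sel]
            # overlap with merged interval j is min(e, me[j]) - max(s, ms[j]);
            # candidate j = first merged interval ending after s + d - 1
            j = np.searchsorted(me, s + d, side="left")
            ok = j < len(ms)
            jj = np.clip(j, 0, max(len(ms) - 1, 0))
            ov = np.minimum(e, me[jj]) - np.maximum(s, ms[jj])
            total += int(np.count_nonzero(ok & (ov >= d)))
        return total


# ---------------------------------------------------------------------------
# Shuffling (permutation null primitive)

def random_placement(
    lengths: np.ndarray, genome: GenomeBuild, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform placement of intervals of the given lengths on the genome.

    Chromosome chosen with probability proportional to the number of feasible
    start positions (chrom_length - L + 1); start uniform among those.
    Returns (chrom_index, start) arrays.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    clens = np.array([n for _, n in genome.chroms], dtype=np.int64)
    w = np.clip(clens[None, :] - lengths[:, None] + 1, 0, None).astype(float)
    tot = w.sum(axis=1)
    if np.any(tot <= 0):
        bad = int(lengths[np.argmax(tot <= 0)])
        raise ValidationError(f"interval of length {bad} longer than every chromosome")
    cum = np.cumsum(w, axis=1)
    u = rng.random(len(lengths)) * tot
    chrom_idx = (cum <= u[:, None]).sum(axis=1)
    feas = clens[chrom_idx] - lengths + 1
    starts = rng.integers(0, feas)
    return chrom_idx, starts


def shuffle(peakset: PeakSet, genome: GenomeBuild, seed: int) -> PeakSet:
    """Length-preserving uniform re-placement of every interval.

    Placed intervals may overlap each other and the original locations;
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([len(iv) for iv in peakset], dtype=np.int64)
    chrom_idx, starts = random_placement(lengths, genome, rng)
    names = [c for c, _ in genome.chroms]
    placed = [
        dataclasses.replace(
            iv, chrom=names[int(ci)], start=int(s), end=int(s) + len(iv)
        )
        for iv, ci, s in zip(peakset, chrom_idx, starts)
    ]
    return PeakSet(placed, label=f"{peakset.label}|shuffled")


# ---------------------------------------------------------------------------
# Gene annotation and nearest-gene assignment

class GeneAnnotation:
    """Gene TSS annotation: records of (gene_id, chrom, tss, strand)."""

    def __init__(self, records: Iterable[tuple[str, str, int, str]]):
        df = pd.DataFrame(records, columns=["gene_id", "chrom", "tss", "strand"])
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        df["tss"] = df["tss"].astype(np.int64)
        self.df = df.reset_index(drop=True)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            self._by_chrom[str(chrom)] = (
                grp["tss"].to_numpy(np.int64),
                grp["gene_id"].to_numpy(object),
            )

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "chrom", "tss", "strand"]
        )
        return cls(df.itertuples(index=False, name=None))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


def two_nearest_genes(
    interval: Interval,
    annotation: GeneAnnotation,
    max_dist: int = 1_000_000,
    mode: Literal["summit", "edge"] = "summit",
) -> list[tuple[str, int]]:
    """The (at most) two nearest genes within max_dist on the same chromosome.

    Distance is |summit - TSS| (``mode='summit'``, the default) or the gap to
    the nearest interval edge with 0 inside (``mode='edge'``).  Sorted by
    ascending distance, ties broken lexicographically by gene_id.
    """
    if len(annotation) == 0:
        raise ValidationError("annotation is empty")
    hit = annotation._by_chrom.get(interval.chrom)
    if hit is None:
        return []
    tss, gene_ids = hit
    if mode == "summit":
        dist = np.abs(tss - summit_position(interval))
    elif mode == "edge":
        dist = np.maximum.reduce(
            [interval.start - tss, tss - (interval.end - 1), np.zeros_like(tss)]
        )
    else:
        raise ValidationError(f"unknown distance mode {mode!r}")
    sel = dist <= max_dist
    pairs = sorted(zip(dist[sel].tolist(), gene_ids[sel].tolist()))
    return [(g, int(d)) for d, g in pairs[:2]]
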