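"""Peak-set co-occupancy: overlap partitions and permutation enrichment.

The overlap partition counts how many intervals of set A overlap at least
one interval of set B (each A interval counted once however many B
intervals it hits), both on the full regions and restricted to summit
+/- k windows.  The permutation null re-places set A uniformly on the
genome (length-preserving shuffle) and recomputes the shared count, giving
a fold enrichment and an add-one empirical p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .intervals import (
    GenomeBuild,
    OverlapCounter,
    PeakSet,
    ValidationError,
    intersect,
    random_placement,
    summit_window,
)

__all__ = [
    "OverlapPartition",
    "EnrichmentResult",
    "percent",
    "overlap_partition",
    "summit_overlap",
    "permutation_enrichment",
]


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100*numerator/denominator rounded half-up to `decimals` places."""
    if denominator <= 0:
        raise ValidationError("denominator must be > 0")
    q = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapPartition:
    """Partition of set A into B-shared and A-only intervals."""

    n_a: int
    n_b: int
    n_shared_a: int
    pct_decimals: int = 2

    @property
    def n_a_only(self) -> int:
        return self.n_a - self.n_shared_a

    @property
    def pct_shared_a(self) -> float:
        return percent(self.n_shared_a, self.n_a, self.pct_decimals)

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_shared_a": self.n_shared_a,
            "n_a_only": self.n_a_only,
            "pct_shared_a": self.pct_shared_a,
        }


@dataclass(frozen=True)
class EnrichmentResult:
    """Permutation fold-enrichment of the shared-interval count."""

    observed: int
    n_perm: int
    perm_mean: float
    perm_sd: float
    fold: float
    empirical_p: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n_perm": self.n_perm,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
            "fold": self.fold,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
        }


def overlap_partition(
    set_a: PeakSet, set_b: PeakSet, min_overlap_bp: int = 1
) -> OverlapPartition:
    """Count A intervals overlapping >=1 B interval by >= min_overlap_bp."""
    if len(set_a) == 0:
        raise ValidationError("set A is empty; shared percentage undefined")
    shared = {i for i, _, _ in intersect(set_a, set_b, min_overlap_bp)}
    return OverlapPartition(len(set_a), len(set_b), len(shared))


def summit_overlap(
    set_a: PeakSet,
    set_b: PeakSet,
    k: int = 6,
    genome: GenomeBuild | None = None,
    min_overlap_bp: int = 1,
) -> OverlapPartition:
    """Overlap partition on summit +/- k windows of both sets.

    Counts refer to the original intervals (windows inherit their indices);
    summits default to midpoints where absent.
    """
    if len(set_a) == 0:
        raise ValidationError("set A is empty; shared percentage undefined")
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    wa = [summit_window(iv, k, genome=genome) for iv in set_a]
    wb = [summit_window(iv, k, genome=genome) for iv in set_b]
    # windows of distinct peaks may coincide, so count over plain lists
    # rather than a (distinct-interval) PeakSet
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in wb:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    b_arrays = {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in by_chrom.items()
    }
    n_shared = 0
    for iv in wa:
        grp = b_arrays.get(iv.chrom)
        if grp is None:
            continue
        starts, ends = grp
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        if np.any(ov >= min_overlap_bp):
            n_shared += 1
    return OverlapPartition(len(set_a), len(set_b), n_shared)


def _iteration_seed(master_seed: int, i: int) -> np.random.Generator:
    # counter-based derivation: independent of iteration order
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(i,))
    return np.random.default_rng(ss)


def permutation_enrichment(
    set_a: PeakSet,
    set_b: PeakSet,
    genome: GenomeBuild,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "shared_count",
) -> EnrichmentResult:
    """Fold enrichment of the observed shared count over shuffled placements.

    For each permutation, set A is re-placed uniformly (length-preserving)
    and the count of A intervals overlapping fixed B is recomputed.
    fold = observed / mean(permuted); empirical p uses the add-one estimator
    (1 + #{perm >= observed}) / (n_perm + 1).  Per-iteration seeds derive
    from the master seed by a counter-based scheme.
    """
    if statistic != "shared_count":
        raise ValidationError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = overlap_partition(set_a, set_b).n_shared_a if len(set_b) else 0
    counter = OverlapCounter(set_b, genome)
    lengths = np.array([len(iv) for iv in set_a], dtype=np.int64)
    counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        rng = _iteration_seed(seed, i)
        chrom_idx, starts = random_placement(lengths, genome, rng)
        counts[i] = counter.count_hits(chrom_idx, starts, lengths)
    perm_mean = float(counts.mean())
    perm_sd = float(counts.std(ddof=1)) if n_perm > 1 else 0.0
    if perm_mean == 0:
        warnings.warn(
            "permutation mean overlap is 0; fold enrichment reported as infinity"
        )
        fold = float("inf") if observed > 0 else float("nan")
    else:
        fold = observed / perm_mean
    empirical_p = (1 + int(np.count_nonzero(counts >= observed))) / (n_perm + 1)
    return EnrichmentResult(observed, n_perm, perm_mean, perm_sd, fold, empirical_p, seed)
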