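"""ChIP x RNA-seq integration: peak-to-gene assignment, differential-
expression filtering, direct-target calling, and 2x2 Fisher contingency
analyses (expression-domain categories; enhancer-validation comparison).

A "direct target" is a gene that is both assigned to a binding region
(among the two nearest genes within 1 Mb of a peak summit) and passes the
differential-expression filter (fold change >= 1.5 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .cooccupancy import percent
from .intervals import (
    GeneAnnotation,
    PeakSet,
    ValidationError,
    two_nearest_genes,
)

__all__ = [
    "DERecord",
    "TargetAssignment",
    "DirectTargetTable",
    "ContingencyResult",
    "read_de_table",
    "read_category_map",
    "assign_targets",
    "filter_de",
    "direct_targets",
    "direction_fractions",
    "fisher_exact_2x2",
    "category_direction_analysis",
    "enhancer_validation_compare",
]


@dataclass(frozen=True)
class DERecord:
    """One differential-expression call."""

    gene_id: str
    log2fc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not (0 <= self.adj_p <= 1):
            raise ValidationError(f"{self.gene_id}: adj_p {self.adj_p} not in [0,1]")

    @property
    def direction(self) -> Literal["up", "down"]:
        return "up" if self.log2fc >= 0 else "down"


@dataclass(frozen=True)
class TargetAssignment:
    region_index: int
    genes: tuple[tuple[str, int], ...]  # (gene_id, distance_bp), <= 2


@dataclass(frozen=True)
class DirectTargetTable:
    """Genes both bound and differentially expressed, with directions."""

    rows: tuple[tuple[str, str, int], ...]  # (gene_id, direction, n_supporting_regions)
    n_bound_only: int
    n_de_only: int

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def n_down(self) -> int:
        return sum(1 for _, d, _ in self.rows if d == "down")

    @property
    def n_up(self) -> int:
        return sum(1 for _, d, _ in self.rows if d == "up")

    @property
    def gene_ids(self) -> set[str]:
        return {g for g, _, _ in self.rows}

    def directions(self) -> dict[str, str]:
        return {g: d for g, d, _ in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["gene_id", "direction", "n_supporting_regions"]
        )


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 exact-test outcome (two-sided hypergeometric rule)."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # (a*d)/(b*c); inf when b*c == 0 and a*d > 0
    p_two_tailed: float

    def to_dict(self) -> dict:
        return {
            "table": [list(r) for r in self.table],
            "odds_ratio": self.odds_ratio,
            "p_two_tailed": self.p_two_tailed,
        }


# ---------------------------------------------------------------------------
# I/O

def read_de_table(path) -> list[DERecord]:
    """TSV of (gene_id, log2fc, adj_p), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "log2fc", "adj_p"])
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(DERecord(str(row.gene_id), float(row.log2fc), float(row.adj_p)))
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"DE table row {i}: {exc}") from None
    return records


def read_category_map(path) -> dict[str, str]:
    """TSV of (gene_id, category), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"])
    return dict(zip(df["gene_id"].astype(str), df["category"].astype(str)))


# ---------------------------------------------------------------------------
# Assignment and integration

def assign_targets(
    peaks: PeakSet,
    annotation: GeneAnnotation,
    max_dist: int = 1_000_000,
    mode: Literal["summit", "edge"] = "summit",
) -> tuple[list[TargetAssignment], set[str]]:
    """Two-nearest-gene assignment per region plus the union of assigned genes."""
    assignments = []
    union: set[str] = set()
    for i, iv in enumerate(peaks):
        genes = tuple(two_nearest_genes(iv, annotation, max_dist=max_dist, mode=mode))
        assignments.append(TargetAssignment(i, genes))
        union.update(g for g, _ in genes)
    return assignments, union


def filter_de(
    de_table: Sequence[DERecord],
    min_fc: float = 1.5,
    max_adj_p: float | None = None,
) -> list[DERecord]:
    """Keep records with |fold change| >= min_fc (inclusive boundary), i.e.
    |log2fc| >= log2(min_fc), and adj_p <= max_adj_p when supplied."""
    if min_fc <= 0:
        raise ValidationError("min_fc must be > 0")
    cut = math.log2(min_fc)
    out = []
    for rec in de_table:
        if abs(rec.log2fc) < cut:
            continue
        if max_adj_p is not None and rec.adj_p > max_adj_p:
            continue
        out.append(rec)
    return out


def direct_targets(
    bound_genes: Iterable[str],
    filtered_de: Sequence[DERecord],
    assignments: Sequence[TargetAssignment] | None = None,
) -> DirectTargetTable:
    """Intersect bound genes with the filtered DE calls.

    Genes supported by several peaks are counted once; the supporting-region
    count is retained when assignments are supplied.  Venn counts
    (bound-only, DE-only, shared) ride along on the result.
    """
    bound = set(bound_genes)
    de_by_gene = {rec.gene_id: rec for rec in filtered_de}
    support: dict[str, int] = {}
    if assignments is not None:
        for a in assignments:
            for g, _ in a.genes:
                support[g] = support.get(g, 0) + 1
    shared = sorted(bound & set(de_by_gene))
    rows = tuple(
        (g, de_by_gene[g].direction, support.get(g, 1)) for g in shared
    )
    return DirectTargetTable(
        rows,
        n_bound_only=len(bound) - len(shared),
        n_de_only=len(de_by_gene) - len(shared),
    )


def direction_fractions(table: DirectTargetTable) -> tuple[float, float]:
    """(pct_down, pct_up) at one decimal."""
    if table.n_total == 0:
        raise ValidationError("direct-target table is empty")
    return (
        percent(table.n_down, table.n_total, 1),
        percent(table.n_up, table.n_total, 1),
    )


# ---------------------------------------------------------------------------
# Exact 2x2 tests

def fisher_exact_2x2(table) -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 table.

    p is the exact hypergeometric two-sided rule (sum of all fixed-margin
    tables at most as probable as the observed one); odds ratio is
    (a*d)/(b*c) with an infinity sentinel when b*c = 0.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(x) != x or x < 0 for x in cells):
        raise ValidationError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        warnings.warn("a margin of the 2x2 table is 0; p defined as 1")
        p = 1.0
    else:
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p = float(min(p, 1.0))
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(((a, b), (c, d)), odds, p)


def category_direction_analysis(
    table: DirectTargetTable,
    category_map: Mapping[str, str],
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-category down/up counts with a Fisher test of category vs rest.

    Each categorized direct target contributes its direction; genes absent
    from the category map are excluded (their count is logged).  For every
    category a 2x2 table [[down_cat, up_cat], [down_rest, up_rest]] is
    tested; an optional Benjamini-Hochberg column is added when
    ``adjust=True``.
    """
    directions = table.directions()
    cat_of = {g: category_map[g] for g in directions if g in category_map}
    n_uncat = len(directions) - len(cat_of)
    if n_uncat:
        warnings.warn(f"{n_uncat} direct targets lack a category; excluded")
    cats = sorted(set(cat_of.values()))
    rows = []
    for cat in cats:
        in_cat = [g for g, c in cat_of.items() if c == cat]
        rest = [g for g in cat_of if cat_of[g] != cat]
        if not in_cat:
            warnings.warn(f"category {cat!r} is empty; skipped")
            continue
        nd = sum(directions[g] == "down" for g in in_cat)
        nu = len(in_cat) - nd
        rd = sum(directions[g] == "down" for g in rest)
        ru = len(rest) - rd
        res = fisher_exact_2x2(((nd, nu), (rd, ru)))
        rows.append(
            {
                "category": cat,
                "n_down": nd,
                "n_up": nu,
                "pct_down": percent(nd, nd + nu, 1),
                "odds_ratio": res.odds_ratio,
                "p_fisher": res.p_two_tailed,
            }
        )
    df = pd.DataFrame(rows)
    if adjust and len(df):
        df["p_bh"] = _benjamini_hochberg(df["p_fisher"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def enhancer_validation_compare(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> tuple[ContingencyResult, float, float]:
    """Compare two (n_active, n_tested) enhancer-validation outcomes.

    Builds the 2x2 (active/inactive x group), returning the Fisher result
    and the two active percentages rounded to 0 decimals.
    """
    (a_act, a_tot), (b_act, b_tot) = group_a, group_b
    if a_tot == 0 or b_tot == 0:
        raise ValidationError("n_tested must be > 0 for both groups")
    if a_act > a_tot or b_act > b_tot:
        raise ValidationError("n_active cannot exceed n_tested")
    res = fisher_exact_2x2(((a_act, a_tot - a_act), (b_act, b_tot - b_act)))
    return res, percent(a_act, a_tot, 0), percent(b_act, b_tot, 0)
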