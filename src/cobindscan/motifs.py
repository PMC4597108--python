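"""Position weight matrices and motif-occurrence analysis.

A PWM is a w x 4 position probability matrix over A,C,G,T with a background
vector; scoring is log2(prob/background) summed over positions ("bits").
The module covers PWM construction from counts, both-strand scanning,
the exact (discretized) null score distribution used to convert a p-value
into a score threshold, composite (overlapping) site detection between two
factors, classification of summit windows into motif-occurrence classes,
and a minimal ZOOPS (zero-or-one-occurrence-per-sequence) EM motif
discoverer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

from .intervals import (
    GenomeBuild,
    Interval,
    PeakSet,
    ValidationError,
    summit_window,
)

__all__ = [
    "ALPHABET",
    "PWM",
    "MotifMatch",
    "CompositeSite",
    "RegionMotifClass",
    "pwm_from_counts",
    "scan",
    "score_distribution",
    "ScoreDistribution",
    "threshold_for_pvalue",
    "detect_composite",
    "classify_regions",
    "discover_motif_zoops_em",
    "read_fasta",
    "write_fasta",
    "read_meme_minimal",
    "write_meme_minimal",
    "read_matrix_tsv",
    "encode_sequence",
    "reverse_complement",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(arr: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in arr)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background and log-odds scores."""

    motif_id: str
    probs: np.ndarray          # (w, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValidationError("probs must be a w x 4 matrix")
        if probs.shape[0] < 4:
            raise ValidationError("PWM width must be >= 4")
        if np.any(probs <= 0) or np.any(probs > 1):
            raise ValidationError("probabilities must lie in (0, 1]; apply a pseudocount")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each PWM row must sum to 1")
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-9:
            raise ValidationError("background must be a length-4 probability vector")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def information_content(self) -> float:
        """Total IC in bits relative to the background."""
        return float((self.probs * self.log_odds).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1], self.background[::-1])


def pwm_from_counts(
    counts: np.ndarray,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
    motif_id: str = "motif",
) -> PWM:
    """Build a PWM from a count matrix.

    The pseudocount is distributed proportionally to the background:
    probs[i,j] = (counts[i,j] + pseudocount*bg[j]) / (rowsum_i + pseudocount).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    probs = (counts + pseudocount * bg[None, :]) / (
        counts.sum(axis=1, keepdims=True) + pseudocount
    )
    return PWM(motif_id, probs, bg)


@dataclass(frozen=True)
class MotifMatch:
    """A scored motif occurrence in forward-strand coordinates."""

    motif_id: str
    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"]
    score: float
    pvalue: float | None = None


@dataclass(frozen=True)
class CompositeSite:
    """Two overlapping occurrences from two PWMs (a candidate shared site)."""

    match_a: MotifMatch
    match_b: MotifMatch
    overlap_bp: int
    offset: int  # start_b - start_a


@dataclass(frozen=True)
class RegionMotifClass:
    region_index: int
    motif_class: Literal["denovo_only", "selex_only", "both", "neither"]


# ---------------------------------------------------------------------------
# Scanning

def _window_scores(lo: np.ndarray, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows; windows containing N masked out.

    Returns (scores, valid) arrays of length len(enc) - w + 1.
    """
    w = lo.shape[0]
    n_win = len(enc) - w + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (win != 4).all(axis=1)
    safe = np.where(win == 4, 0, win)
    scores = lo[np.arange(w)[None, :], safe].sum(axis=1)
    return scores, valid


def scan(
    pwm: PWM,
    sequence: str,
    score_threshold: float,
    strands: Literal["both", "forward"] = "both",
    chrom: str = "seq",
    offset: int = 0,
    score_dist: "ScoreDistribution | None" = None,
) -> list[MotifMatch]:
    """All windows scoring >= score_threshold, in forward coordinates.

    The reverse strand is scored on the reverse complement (equivalently,
    with the reverse-complemented PWM on the forward sequence); windows
    containing N are skipped.  ``offset`` shifts reported coordinates, for
    scanning an excised subsequence of a chromosome.
    """
    enc = encode_sequence(sequence)
    w = pwm.width
    out: list[MotifMatch] = []
    strand_los = [("+", pwm.log_odds)]
    if strands == "both":
        strand_los.append(("-", pwm.reverse_complement().log_odds))
    elif strands != "forward":
        raise ValidationError(f"unknown strands option {strands!r}")
    tol = 1e-9
    for strand, lo in strand_los:
        scores, valid = _window_scores(lo, enc)
        for pos in np.nonzero(valid & (scores >= score_threshold - tol))[0]:
            s = float(scores[pos])
            out.append(
                MotifMatch(
                    pwm.motif_id,
                    chrom,
                    offset + int(pos),
                    offset + int(pos) + w,
                    strand,  # type: ignore[arg-type]
                    s,
                    pvalue=score_dist.sf(s) if score_dist is not None else None,
                )
            )
    out.sort(key=lambda m: (m.start, m.strand))
    return out


# ---------------------------------------------------------------------------
# Exact score distribution and p-value thresholds

@dataclass(frozen=True)
class ScoreDistribution:
    """Exact distribution of the rounded log-odds score of a background window.

    Scores are rounded to integer multiples of ``granularity`` before the
    positional convolution; bin i holds score (offset + i) * granularity.
    """

    granularity: float
    offset: int
    pmf: np.ndarray

    @property
    def scores(self) -> np.ndarray:
        return (self.offset + np.arange(len(self.pmf))) * self.granularity

    @property
    def _sf(self) -> np.ndarray:
        return self.pmf[::-1].cumsum()[::-1]

    def sf(self, score: float) -> float:
        """P(rounded score >= score)."""
        k = int(round(score / self.granularity)) - self.offset
        if k <= 0:
            return 1.0
        if k >= len(self.pmf):
            return 0.0
        return float(self._sf[k])

    def threshold_for_pvalue(self, p: float) -> float:
        """Smallest score s with P(score >= s) <= p.

        p = 1 returns the minimum attainable score.  If even the best single
        outcome has mass > p, no finite threshold qualifies and +inf is
        returned, so a scan at that threshold reports nothing.
        """
        if not (0 < p <= 1):
            raise ValidationError("p must be in (0, 1]")
        sf = self._sf
        ok = np.nonzero(sf <= p)[0]
        if len(ok) == 0:
            return float("inf")
        return float((self.offset + int(ok[0])) * self.granularity)


def score_distribution(
    pwm: PWM, background: np.ndarray | None = None, granularity: float = 1e-3
) -> ScoreDistribution:
    """Exact null score distribution by positional convolution (DP)."""
    if granularity <= 0:
        raise ValidationError("granularity must be > 0")
    bg = pwm.background if background is None else np.asarray(background, float)
    q = np.rint(pwm.log_odds / granularity).astype(np.int64)  # (w, 4)
    pmf = np.ones(1)
    offset = 0
    for i in range(pwm.width):
        qi = q[i]
        lo, hi = int(qi.min()), int(qi.max())
        new = np.zeros(len(pmf) + hi - lo)
        for j in range(4):
            new[qi[j] - lo : qi[j] - lo + len(pmf)] += bg[j] * pmf
        pmf = new
        offset += lo
    assert abs(pmf.sum() - 1) < 1e-9
    return ScoreDistribution(granularity, offset, pmf)


def threshold_for_pvalue(dist: ScoreDistribution, p: float) -> float:
    return dist.threshold_for_pvalue(p)


# ---------------------------------------------------------------------------
# Composite sites

def detect_composite(
    matches_a: Sequence[MotifMatch],
    matches_b: Sequence[MotifMatch],
    min_overlap_bp: int = 1,
    max_abs_offset: int | None = None,
) -> list[CompositeSite]:
    """All overlapping pairs of occurrences from two factors.

    A pair qualifies when the two match intervals share >= min_overlap_bp
    bases and |start_b - start_a| <= max_abs_offset (default: width of the
    first factor's matches).
    """
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    out = []
    for ma in matches_a:
        wa = ma.end - ma.start
        limit = wa if max_abs_offset is None else max_abs_offset
        for mb in matches_b:
            if ma.chrom != mb.chrom:
                continue
            ov = min(ma.end, mb.end) - max(ma.start, mb.start)
            off = mb.start - ma.start
            if ov >= min_overlap_bp and abs(off) <= limit:
                out.append(CompositeSite(ma, mb, ov, off))
    return out


# ---------------------------------------------------------------------------
# Region classification

def classify_regions(
    regions: PeakSet,
    genome_sequence: dict[str, str],
    pwm_selex: PWM,
    pwm_denovo: PWM,
    k: int = 25,
    p_threshold: float = 1e-4,
    genome: GenomeBuild | None = None,
    strands: Literal["both", "forward"] = "both",
    granularity: float = 1e-3,
) -> tuple[list[RegionMotifClass], dict[str, float]]:
    """Classify each region's summit +/- k window by motif occurrence.

    Each window is scanned with both PWMs at the score threshold matching
    ``p_threshold`` under the exact background score distribution (FIMO-style
    semantics).  Classes are mutually exclusive and exhaustive:
    both / denovo_only / selex_only / neither.  The summary reports the
    marginal fractions ("with de novo" = both + denovo_only, likewise selex)
    and the four class fractions, as percentages at one decimal.
    """
    from .cooccupancy import percent

    thresholds = {}
    for pwm in (pwm_selex, pwm_denovo):
        dist = score_distribution(pwm, granularity=granularity)
        thresholds[pwm.motif_id] = dist.threshold_for_pvalue(p_threshold)
    classes: list[RegionMotifClass] = []
    counts = {"denovo_only": 0, "selex_only": 0, "both": 0, "neither": 0}
    for i, region in enumerate(regions):
        if region.chrom not in genome_sequence:
            raise ValidationError(
                f"region {i} ({region.chrom}:{region.start}-{region.end}): "
                f"chromosome {region.chrom!r} absent from genome sequence"
            )
        wnd = summit_window(region, k, genome=genome)
        seq = genome_sequence[region.chrom][wnd.start : wnd.end]
        has = {}
        for pwm in (pwm_selex, pwm_denovo):
            has[pwm.motif_id] = bool(
                scan(pwm, seq, thresholds[pwm.motif_id], strands=strands)
            )
        sel, dnv = has[pwm_selex.motif_id], has[pwm_denovo.motif_id]
        cls = (
            "both" if sel and dnv
            else "selex_only" if sel
            else "denovo_only" if dnv
            else "neither"
        )
        counts[cls] += 1
        classes.append(RegionMotifClass(i, cls))  # type: ignore[arg-type]
    n = len(regions)
    summary = {
        "n_regions": float(n),
        "pct_denovo": percent(counts["both"] + counts["denovo_only"], n, 1),
        "pct_selex": percent(counts["both"] + counts["selex_only"], n, 1),
        "pct_both": percent(counts["both"], n, 1),
        "pct_neither": percent(counts["neither"], n, 1),
        **{f"n_{k_}": float(v) for k_, v in counts.items()},
    }
    return classes, summary


# ---------------------------------------------------------------------------
# ZOOPS EM motif discovery (minimal de novo stand-in)

def discover_motif_zoops_em(
    sequences: Sequence[str],
    width: int,
    n_starts: int = 5,
    seed: int = 0,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    motif_id: str = "zoops",
) -> PWM:
    """De novo motif discovery under the ZOOPS model by EM.

    Each sequence carries zero or one motif occurrence (forward strand).
    The E-step computes per-sequence posteriors over (no site, site at each
    offset); the M-step re-estimates the PWM from expected base counts with
    background-proportional pseudocounts and the site prior gamma from the
    mean posterior occupancy.  ``n_starts`` seeded restarts initialize from
    randomly chosen sequence windows; the highest-likelihood PWM wins.
    Deterministic for a given seed.
    """
    if width < 4:
        raise ValidationError("width must be >= 4")
    if any(len(s) < width for s in sequences):
        raise ValidationError("every sequence must be at least `width` long")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)

    windows = []
    seq_id = []
    for si, s in enumerate(sequences):
        enc = encode_sequence(s)
        if np.any(enc == 4):
            raise ValidationError("sequences must be over A,C,G,T (no N)")
        win = np.lib.stride_tricks.sliding_window_view(enc, width)
        windows.append(win)
        seq_id.append(np.full(len(win), si))
    X = np.concatenate(windows)                       # (n_win_total, width)
    sid = np.concatenate(seq_id)
    n_seq = len(sequences)
    n_off = np.bincount(sid, minlength=n_seq).astype(float)
    onehot = np.eye(4)[X]                             # (n_win, width, 4)
    log_bg_win = np.log(bg)[X].sum(axis=1)            # per-window bg log prob

    def run_em(probs0: np.ndarray) -> tuple[float, np.ndarray]:
        probs = probs0
        gamma = 0.5
        prev_ll = -np.inf
        for _ in range(max_iter):
            log_site = np.log(probs)[np.arange(width)[None, :], X].sum(axis=1)
            log_r = log_site - log_bg_win             # per-window LLR
            # per-sequence mixture: (1-gamma) + (gamma/n_off) * sum exp(log_r)
            m = np.zeros(n_seq)
            np.maximum.at(m, sid, log_r)
            rexp = np.exp(log_r - m[sid])
            ssum = np.zeros(n_seq)
            np.add.at(ssum, sid, rexp)
            z_site_seq = (gamma / n_off) * np.exp(m) * ssum
            denom = (1 - gamma) + z_site_seq
            ll = float(np.log(denom).sum() + 0.0)     # + sum log P(seq|bg), const
            # posterior weight of each window
            w_win = (gamma / n_off[sid]) * np.exp(m[sid]) * rexp / denom[sid]
            counts = np.einsum("n,nwb->wb", w_win, onehot)
            probs = (counts + pseudocount * bg[None, :]) / (
                counts.sum(axis=1, keepdims=True) + pseudocount
            )
            gamma = float(np.clip((z_site_seq / denom).mean(), 1e-3, 1 - 1e-3))
            if ll - prev_ll < tol and ll >= prev_ll:
                prev_ll = ll
                break
            prev_ll = ll
        return prev_ll, probs

    def shift_refine(ll: float, probs: np.ndarray) -> tuple[float, np.ndarray]:
        # phase-shift moves: EM converges readily to a 1-bp-shifted optimum;
        # restart from the column-shifted matrix and keep any improvement
        improved = True
        while improved:
            improved = False
            for step in (-1, 1):
                shifted = np.roll(probs, step, axis=0)
                fill = 0 if step > 0 else width - 1
                shifted[fill] = bg
                ll2, probs2 = run_em(shifted)
                if ll2 > ll + 1e-9:
                    ll, probs = ll2, probs2
                    improved = True
        return ll, probs

    best_ll, best_probs = -np.inf, None
    for _ in range(max(1, n_starts)):
        start_win = X[rng.integers(0, len(X))]
        probs0 = np.full((width, 4), 0.1)
        probs0[np.arange(width), start_win] = 0.7
        ll, probs = shift_refine(*run_em(probs0))
        if ll > best_ll:
            best_ll, best_probs = ll, probs
    assert best_probs is not None
    return PWM(f"{motif_id}_w{width}", best_probs, bg)


# ---------------------------------------------------------------------------
# Sequence and PWM file I/O

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_meme_minimal(pwms: Sequence[PWM], path) -> None:
    """Write PWMs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else UNIFORM_BACKGROUND
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.10f}" for p in row) + "\n")
            fh.write("\n")


def read_meme_minimal(path) -> list[PWM]:
    """Parse MEME minimal text format (probability matrices only)."""
    pwms: list[PWM] = []
    bg = UNIFORM_BACKGROUND.copy()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            bg = np.array([float(toks[2 * _BASE_INDEX[b] + 1]) for b in ALPHABET])
            i += 2
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            rowmat = np.array(rows)
            rowmat /= rowmat.sum(axis=1, keepdims=True)  # absorb print rounding
            pwms.append(PWM(motif_id, rowmat, bg))
            i += 1 + w
        else:
            i += 1
    return pwms


def read_matrix_tsv(
    path,
    motif_id: str | None = None,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> PWM:
    """Plain whitespace-delimited w x 4 matrix (counts or probabilities).

    Rows are positions, columns A C G T (an optional header row is allowed).
    Count matrices (rows not summing to ~1) pass through pwm_from_counts.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks or toks[0].upper() == "A":
                continue
            rows.append([float(t) for t in toks])
    mat = np.array(rows)
    mid = motif_id or str(path)
    if np.allclose(mat.sum(axis=1), 1.0, atol=1e-3):
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
        return PWM(mid, mat, bg)
    return pwm_from_counts(mat, pseudocount=pseudocount, background=background, motif_id=mid)
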