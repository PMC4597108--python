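"""Synthetic genome / peak / expression generator with planted ground truth.

The generator emulates the statistical structure of a paired-factor
co-occupancy study: a small multi-chromosome genome, two peak sets with a
controlled shared fraction and summit jitter, motif instances planted by
substring substitution at peak summits (so high-threshold scans recover
them exactly), a TSS annotation, and a differential-expression table in
which a subset of bound genes is dysregulated with known directions and
expression-domain categories.  Everything planted is recorded in a
machine-readable truth object that an audit routine re-verifies against
the emitted files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cooccupancy import percent
from .intervals import (
    GeneAnnotation,
    GenomeBuild,
    Interval,
    PeakSet,
    ValidationError,
    intersect,
    read_bed,
    read_chrom_sizes,
    write_bed,
)
from .motifs import PWM, decode_sequence, encode_sequence, read_fasta, write_fasta, write_meme_minimal

__all__ = [
    "SELEX_CONSENSUS",
    "MEIS_CONSENSUS",
    "SimConfig",
    "SimTruth",
    "AuditReport",
    "build_hybrid_consensus",
    "consensus_pwm",
    "generate",
    "audit",
]

# Selex-like NKX2-5 core (AAGTG) in a 7-mer, and a MEIS-like TGACAG core.
SELEX_CONSENSUS = "CAAGTGG"
MEIS_CONSENSUS = "CTGACAG"

_CLASSES = ("denovo_only", "selex_only", "both", "neither")


def build_hybrid_consensus(
    selex: str = SELEX_CONSENSUS, meis: str = MEIS_CONSENSUS, offset: int = 4
) -> str:
    """Composite site: 5' selex-like half overlapping the MEIS 3' site.

    The MEIS consensus is written starting ``offset`` bases into the selex
    consensus; overlapping positions take the MEIS bases, so the 3' portion
    matches MEIS exactly while the 5' stays similar to (not identical with)
    the selex motif.
    """
    if not (0 < offset < len(selex)):
        raise ValidationError("hybrid offset must lie inside the selex consensus")
    return selex[:offset] + meis


def consensus_pwm(
    consensus: str,
    motif_id: str,
    p_major: float = 0.94,
    background: np.ndarray | None = None,
) -> PWM:
    """A sharply peaked PWM whose consensus string is the given sequence."""
    idx = encode_sequence(consensus)
    probs = np.full((len(consensus), 4), (1 - p_major) / 3)
    probs[np.arange(len(consensus)), idx] = p_major
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(motif_id, probs, bg)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _exact_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n among the keys."""
    keys = list(proportions)
    raw = np.array([proportions[k] for k in keys], dtype=float)
    if abs(raw.sum() - 1) > 1e-9:
        raise ValidationError("proportions must sum to 1")
    exact = raw * n
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a tenfold scale-down of the motivating study: 261
    binding regions for factor A against 600 for factor B with shared
    fraction 0.2931, summit jitter SD 20 bp, a 50/40/5/5 motif-class mix in
    the A summit windows, and ~9.3% of bound genes planted as direct
    targets with a chamber-restricted down-regulation bias.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 500_000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_major: float = 0.94
    hybrid_offset: int = 4
    n_peaks_a: int = 261
    n_peaks_b: int = 600
    shared_fraction: float = 0.2931
    peak_width: int = 200
    summit_jitter_sd: float = 20.0
    class_mix: dict = field(
        default_factory=lambda: {
            "denovo_only": 0.50, "selex_only": 0.40, "both": 0.05, "neither": 0.05,
        }
    )
    n_genes: int = 400
    de_fraction_of_bound: float = 0.093
    unbound_de_fraction: float = 0.35
    fraction_down_unbound: float = 0.5
    log2fc_range: tuple[float, float] = (0.7, 2.5)
    category_mix: dict = field(
        default_factory=lambda: {"AVC": 0.30, "chamber": 0.20, "pan": 0.50}
    )
    category_down_bias: dict = field(
        default_factory=lambda: {"AVC": 0.5, "chamber": 0.8, "pan": 0.5}
    )

    def __post_init__(self) -> None:
        if not (0 <= self.shared_fraction <= 1):
            raise ValidationError("shared_fraction must lie in [0, 1]")
        if abs(sum(self.class_mix.values()) - 1) > 1e-9:
            raise ValidationError("class_mix must sum to 1")
        if abs(sum(self.category_mix.values()) - 1) > 1e-9:
            raise ValidationError("category_mix must sum to 1")
        if abs(sum(self.background) - 1) > 1e-9:
            raise ValidationError("background must sum to 1")

    @property
    def n_shared(self) -> int:
        # rounding rule: half-up, recorded in truth
        return _round_half_up(self.shared_fraction * self.n_peaks_a)

    def pwms(self) -> dict[str, PWM]:
        bg = np.asarray(self.background)
        return {
            "selex": consensus_pwm(SELEX_CONSENSUS, "selex", self.p_major, bg),
            "meis": consensus_pwm(MEIS_CONSENSUS, "meis", self.p_major, bg),
            "denovo": consensus_pwm(
                build_hybrid_consensus(offset=self.hybrid_offset),
                "denovo", self.p_major, bg,
            ),
        }


@dataclass
class SimTruth:
    """Everything the generator planted, keyed by emitted names."""

    config: dict
    n_shared: int
    pct_shared_a: float
    shared_pairs: list  # [a_name, b_name, abs_summit_distance]
    n_direct_summit_k6: int
    classes: dict       # a_name -> class
    class_counts: dict
    planted_sites: list  # {peak, motif, rel_start (to summit), seq}
    bound_genes: list
    targets: dict       # gene -> {direction, category, log2fc, adj_p}
    n_targets: int
    n_down: int
    n_up: int
    category_counts: dict  # cat -> {down, up}
    de_only_genes: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class AuditReport:
    passed: bool
    failures: tuple[str, ...]


def generate(config: SimConfig, out_dir) -> dict[str, Path]:
    """Emit the full synthetic dataset and its truth record.

    Returns a dict of output paths: genome_fasta, chrom_sizes, peaks_a,
    peaks_b, annotation, de_table, categories, pwms, truth.
    Deterministic (bit-identical files) for identical (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background, dtype=float)
    w = config.peak_width
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = GenomeBuild(
        "synthetic", tuple((c, config.chrom_length) for c in chrom_names)
    )

    # --- genome sequence ----------------------------------------------------
    seqs = {
        c: rng.choice(4, size=config.chrom_length, p=bg).astype(np.int8)
        for c in chrom_names
    }

    # --- peak placement on non-overlapping slots ----------------------------
    margin = 300  # keeps summit windows of neighbouring slots apart
    slot_w = w + 2 * margin
    slots = [
        (c, s)
        for c in chrom_names
        for s in range(0, config.chrom_length - slot_w + 1, slot_w)
    ]
    n_shared = config.n_shared
    n_a_only = config.n_peaks_a - n_shared
    need = config.n_peaks_b + n_a_only
    if need > len(slots):
        raise ValidationError(
            f"infeasible config: {need} non-overlapping peaks requested but only "
            f"{len(slots)} slots fit on the genome"
        )
    slot_idx = rng.choice(len(slots), size=need, replace=False)

    def make_peak(name: str, slot: tuple[str, int], summit_off: int) -> Interval:
        chrom, s0 = slot
        start = s0 + margin
        return Interval(chrom, start, start + w, name=name, summit=summit_off)

    peaks_b: list[Interval] = []
    for i in range(config.n_peaks_b):
        off = w // 2 + int(rng.integers(-10, 11))
        peaks_b.append(make_peak(f"b_{i + 1:04d}", slots[slot_idx[i]], off))

    peaks_a: list[Interval] = []
    shared_b_idx = rng.choice(config.n_peaks_b, size=n_shared, replace=False)
    shared_pairs: list[list] = []
    for j, bi in enumerate(shared_b_idx):
        bpk = peaks_b[int(bi)]
        jitter = int(np.rint(rng.normal(0.0, config.summit_jitter_sd)))
        summit = int(np.clip(bpk.summit + jitter, 40, w - 41))
        apk = Interval(bpk.chrom, bpk.start, bpk.end, name=f"a_{j + 1:04d}", summit=summit)
        peaks_a.append(apk)
        shared_pairs.append([apk.name, bpk.name, abs(summit - bpk.summit)])
    for i in range(n_a_only):
        off = w // 2 + int(rng.integers(-10, 11))
        peaks_a.append(
            make_peak(f"a_{n_shared + i + 1:04d}", slots[slot_idx[config.n_peaks_b + i]], off)
        )

    # --- motif planting -----------------------------------------------------
    hybrid = build_hybrid_consensus(offset=config.hybrid_offset)
    class_counts = _exact_counts(config.n_peaks_a, config.class_mix)
    class_labels = [c for c in _CLASSES for _ in range(class_counts[c])]
    class_labels = [class_labels[i] for i in rng.permutation(config.n_peaks_a)]

    planted_sites: list[dict] = []

    def plant(peak: Interval, motif_name: str, seq: str, rel_start: int) -> None:
        pos = peak.start + peak.summit + rel_start
        seqs[peak.chrom][pos : pos + len(seq)] = encode_sequence(seq)
        planted_sites.append(
            {"peak": peak.name, "motif": motif_name, "rel_start": rel_start, "seq": seq}
        )

    classes: dict[str, str] = {}
    for peak, cls in zip(peaks_a, class_labels):
        classes[peak.name] = cls
        if cls in ("denovo_only", "both"):
            plant(peak, "denovo", hybrid, -(len(hybrid) // 2))
        if cls in ("selex_only",):
            plant(peak, "selex", SELEX_CONSENSUS, -(len(SELEX_CONSENSUS) // 2))
        if cls == "both":
            plant(peak, "selex", SELEX_CONSENSUS, -20)
    shared_b_names = {peaks_b[int(bi)].name for bi in shared_b_idx}
    for peak in peaks_b:
        if peak.name not in shared_b_names:  # shared regions carry the A-class site
            plant(peak, "meis", MEIS_CONSENSUS, -(len(MEIS_CONSENSUS) // 2))

    # --- gene annotation ----------------------------------------------------
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    gene_chrom = [chrom_names[int(i)] for i in rng.integers(0, config.n_chroms, config.n_genes)]
    gene_tss = rng.integers(0, config.chrom_length, config.n_genes)
    gene_strand = ["+" if u < 0.5 else "-" for u in rng.random(config.n_genes)]
    annotation = GeneAnnotation(zip(gene_ids, gene_chrom, gene_tss.tolist(), gene_strand))

    # bound set by the generator's own exhaustive scan (independent of the
    # pipeline's assignment code): two nearest genes within 1 Mb per A peak
    bound: set[str] = set()
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g, c, t in zip(gene_ids, gene_chrom, gene_tss.tolist()):
        by_chrom.setdefault(c, []).append((t, g))
    for peak in peaks_a:
        summit_abs = peak.start + peak.summit
        cand = sorted(
            (abs(t - summit_abs), g)
            for t, g in by_chrom.get(peak.chrom, [])
            if abs(t - summit_abs) <= 1_000_000
        )
        bound.update(g for _, g in cand[:2])

    # --- differential expression -------------------------------------------
    bound_sorted = sorted(bound)
    n_targets = _round_half_up(config.de_fraction_of_bound * len(bound_sorted))
    target_genes = sorted(
        np.array(bound_sorted, dtype=object)[
            rng.choice(len(bound_sorted), size=n_targets, replace=False)
        ].tolist()
    )
    cat_counts = _exact_counts(n_targets, config.category_mix)
    cat_labels = [c for c in sorted(cat_counts) for _ in range(cat_counts[c])]
    cat_labels = [cat_labels[i] for i in rng.permutation(n_targets)]

    lo_fc, hi_fc = config.log2fc_range
    targets: dict[str, dict] = {}
    category_counts = {c: {"down": 0, "up": 0} for c in config.category_mix}
    for g, cat in zip(target_genes, cat_labels):
        down = bool(rng.random() < config.category_down_bias[cat])
        mag = float(rng.uniform(lo_fc, hi_fc))
        targets[g] = {
            "direction": "down" if down else "up",
            "category": cat,
            "log2fc": -mag if down else mag,
            "adj_p": float(rng.uniform(0.0, 0.01)),
        }
        category_counts[cat]["down" if down else "up"] += 1

    unbound = sorted(set(gene_ids) - bound)
    n_de_unbound = _round_half_up(config.unbound_de_fraction * len(unbound))
    de_only = sorted(
        np.array(unbound, dtype=object)[
            rng.choice(len(unbound), size=n_de_unbound, replace=False)
        ].tolist()
    ) if unbound else []
    de_rows: dict[str, tuple[float, float]] = {}
    for g in de_only:
        down = bool(rng.random() < config.fraction_down_unbound)
        mag = float(rng.uniform(lo_fc, hi_fc))
        de_rows[g] = (-mag if down else mag, float(rng.uniform(0.0, 0.01)))
    for g in gene_ids:
        if g in targets:
            de_rows[g] = (targets[g]["log2fc"], targets[g]["adj_p"])
        elif g not in de_rows:
            de_rows[g] = (
                float(rng.uniform(-0.4, 0.4)),
                float(rng.uniform(0.2, 1.0)),
            )

    # --- emit files ---------------------------------------------------------
    paths = {
        "genome_fasta": out / "genome.fa",
        "chrom_sizes": out / "genome.chrom.sizes",
        "peaks_a": out / "peaks_a.narrowPeak",
        "peaks_b": out / "peaks_b.narrowPeak",
        "annotation": out / "genes.tsv",
        "de_table": out / "de_table.tsv",
        "categories": out / "categories.tsv",
        "pwms": out / "motifs.meme",
        "truth": out / "truth.json",
    }
    write_fasta({c: decode_sequence(seqs[c]) for c in chrom_names}, paths["genome_fasta"])
    with open(paths["chrom_sizes"], "w") as fh:
        for c in chrom_names:
            fh.write(f"{c}\t{config.chrom_length}\n")
    write_bed(PeakSet(peaks_a, label="peaks_a"), paths["peaks_a"], "narrowPeak")
    write_bed(PeakSet(peaks_b, label="peaks_b"), paths["peaks_b"], "narrowPeak")
    annotation.write_tsv(paths["annotation"])
    with open(paths["de_table"], "w") as fh:
        for g in gene_ids:
            fc, p = de_rows[g]
            fh.write(f"{g}\t{fc:.6f}\t{p:.6f}\n")
    with open(paths["categories"], "w") as fh:
        for g in target_genes:
            fh.write(f"{g}\t{targets[g]['category']}\n")
    write_meme_minimal(list(config.pwms().values()), paths["pwms"])

    n_direct = sum(1 for _, _, d in shared_pairs if d <= 12)  # +/-6 bp windows touch
    truth = SimTruth(
        config=dataclasses.asdict(config),
        n_shared=n_shared,
        pct_shared_a=percent(n_shared, config.n_peaks_a),
        shared_pairs=shared_pairs,
        n_direct_summit_k6=n_direct,
        classes=classes,
        class_counts=class_counts,
        planted_sites=planted_sites,
        bound_genes=bound_sorted,
        targets=targets,
        n_targets=n_targets,
        n_down=sum(1 for t in targets.values() if t["direction"] == "down"),
        n_up=sum(1 for t in targets.values() if t["direction"] == "up"),
        category_counts=category_counts,
        de_only_genes=de_only,
    )
    truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Self-audit

def audit(truth: SimTruth, paths: dict) -> AuditReport:
    """Re-read the emitted files and verify every planted assertion.

    Checks: each planted motif substring sits at its summit-relative
    position in the genome; the A/B overlap count and pair identities are
    exact; DE signs, magnitudes and adjusted p-values are consistent with
    the planted targets; non-target genes stay below the DE thresholds.
    """
    failures: list[str] = []
    genome_seq = read_fasta(paths["genome_fasta"])
    set_a = read_bed(paths["peaks_a"], "narrowPeak", label="A")
    set_b = read_bed(paths["peaks_b"], "narrowPeak", label="B")
    genome = read_chrom_sizes(paths["chrom_sizes"])
    set_a.validate_against(genome)
    set_b.validate_against(genome)
    a_by_name = {iv.name: iv for iv in set_a}
    b_by_name = {iv.name: iv for iv in set_b}

    for site in truth.planted_sites:
        peak = a_by_name.get(site["peak"]) or b_by_name.get(site["peak"])
        if peak is None:
            failures.append(f"planted site: peak {site['peak']} missing from files")
            continue
        pos = peak.start + peak.summit + site["rel_start"]
        found = genome_seq[peak.chrom][pos : pos + len(site["seq"])]
        if found != site["seq"]:
            failures.append(
                f"planted {site['motif']} site at peak {site['peak']}: "
                f"expected {site['seq']} at {peak.chrom}:{pos}, found {found}"
            )

    pairs = intersect(set_a, set_b)
    shared_names = {
        (set_a[i].name, set_b[j].name) for i, j, _ in pairs
    }
    expect = {(a, b) for a, b, _ in truth.shared_pairs}
    if shared_names != expect:
        extra = sorted(shared_names - expect)
        missing = sorted(expect - shared_names)
        failures.append(
            f"overlap pairs differ from truth (extra={extra[:5]}, missing={missing[:5]})"
        )
    if len({i for i, _, _ in pairs}) != truth.n_shared:
        failures.append(
            f"shared count {len({i for i, _, _ in pairs})} != planted {truth.n_shared}"
        )

    de = {}
    with open(paths["de_table"]) as fh:
        for line in fh:
            g, fc, p = line.split("\t")
            de[g] = (float(fc), float(p))
    min_l2fc = np.log2(1.5)
    for g, t in truth.targets.items():
        fc, p = de.get(g, (None, None))
        if fc is None:
            failures.append(f"target gene {g} missing from DE table")
            continue
        direction = "down" if fc < 0 else "up"
        if direction != t["direction"]:
            failures.append(
                f"gene {g}: DE direction {direction} != planted {t['direction']}"
            )
        if abs(fc) < min_l2fc or p > 0.01:
            failures.append(f"gene {g}: planted target below DE thresholds")
    de_called = set(truth.targets) | set(truth.de_only_genes)
    for g, (fc, p) in de.items():
        if g not in de_called and (abs(fc) >= min_l2fc and p <= 0.05):
            failures.append(f"gene {g}: unplanted gene passes the DE filter")

    return AuditReport(passed=not failures, failures=tuple(failures))
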