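"""End-to-end pipeline: motif classification, co-occupancy, enrichment,
and target integration, with stage caching and a consolidated report.

All thresholds live in :class:`PipelineConfig`; every stage logs one
structured line (input counts, output counts, elapsed time) and caches its
JSON-serializable output under a content hash of its inputs, so re-running
with unchanged inputs reuses the cached result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cooccupancy import overlap_partition, permutation_enrichment, summit_overlap
from .intervals import (
    GeneAnnotation,
    ValidationError,
    read_bed,
    read_chrom_sizes,
)
from .motifs import classify_regions, read_fasta, read_meme_minimal
from .targets import (
    assign_targets,
    category_direction_analysis,
    direct_targets,
    direction_fractions,
    filter_de,
    read_category_map,
    read_de_table,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cobindscan")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and thresholds for a full analysis run."""

    genome_fasta: str
    chrom_sizes: str
    peaks_a: str
    peaks_b: str
    annotation: str
    de_table: str | None
    pwm_file: str
    out_dir: str
    categories: str | None = None
    selex_motif: str = "selex"
    denovo_motif: str = "denovo"
    k_motif: int = 25
    k_summit: int = 6
    max_dist: int = 1_000_000
    n_perm: int = 10_000
    p_scan: float = 1e-4
    min_fc: float = 1.5
    max_adj_p: float = 0.05
    distance_mode: str = "summit"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_motif", "k_summit", "max_dist", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.p_scan <= 1):
            raise ValidationError("p_scan must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_parts(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (str, Path)) and Path(str(p)).is_file():
            h.update(Path(str(p)).read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


class _Stage:
    """Runs a stage with logging, error naming, and content-hash caching."""

    def __init__(self, cache_dir: Path):
        self.cache_dir = cache_dir
        cache_dir.mkdir(parents=True, exist_ok=True)

    def run(self, name: str, key_parts, fn, n_in: int | None = None):
        cache_file = self.cache_dir / f"{name}_{_hash_parts(name, *key_parts)}.json"
        t0 = time.perf_counter()
        if cache_file.is_file():
            with open(cache_file) as fh:
                out = json.load(fh)
            log.info("stage=%s cached=yes elapsed=%.3fs", name, time.perf_counter() - t0)
            return out
        try:
            out = fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        with open(cache_file, "w") as fh:
            json.dump(out, fh, sort_keys=True)
        log.info(
            "stage=%s cached=no n_in=%s elapsed=%.3fs",
            name, n_in, time.perf_counter() - t0,
        )
        return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every analysis stage and write report.json / report.tsv.

    Stage order: classify_regions -> overlap_partition -> summit_overlap ->
    permutation_enrichment -> assign_targets -> filter_de -> direct_targets
    -> direction_fractions -> category_direction_analysis.  The report
    contains every intermediate count, percentage, fold and p-value, plus
    the tool version and a config echo; reports are byte-identical across
    reruns with the same config.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = _Stage(out_dir / "cache")

    if config.de_table is None:
        raise PipelineError(
            "stage 'config' failed: de_table path is required for target integration"
        )

    genome = read_chrom_sizes(config.chrom_sizes)
    genome_seq = read_fasta(config.genome_fasta)
    set_a = read_bed(config.peaks_a, "narrowPeak", label="A")
    set_b = read_bed(config.peaks_b, "narrowPeak", label="B")
    set_a.validate_against(genome)
    set_b.validate_against(genome)
    annotation = GeneAnnotation.read_tsv(config.annotation)
    pwms = {p.motif_id: p for p in read_meme_minimal(config.pwm_file)}
    for key in (config.selex_motif, config.denovo_motif):
        if key not in pwms:
            raise PipelineError(f"stage 'load' failed: motif {key!r} not in PWM file")

    report: dict = {
        "tool": "cobindscan",
        "version": __version__,
        "config": config.to_dict(),
        "n_peaks_a": len(set_a),
        "n_peaks_b": len(set_b),
        "n_genes": len(annotation),
    }

    def _classify():
        classes, summary = classify_regions(
            set_a, genome_seq, pwms[config.selex_motif], pwms[config.denovo_motif],
            k=config.k_motif, p_threshold=config.p_scan, genome=genome,
        )
        return {
            "classes": {set_a[c.region_index].name or str(c.region_index): c.motif_class
                        for c in classes},
            "summary": summary,
        }

    report["motif_classes"] = stage.run(
        "classify",
        [config.peaks_a, config.genome_fasta, config.pwm_file,
         config.k_motif, config.p_scan],
        _classify, n_in=len(set_a),
    )

    report["overlap"] = stage.run(
        "overlap", [config.peaks_a, config.peaks_b],
        lambda: overlap_partition(set_a, set_b).to_dict(), n_in=len(set_a),
    )
    report["summit_overlap"] = stage.run(
        "summit_overlap", [config.peaks_a, config.peaks_b, config.k_summit],
        lambda: summit_overlap(set_a, set_b, k=config.k_summit, genome=genome).to_dict(),
        n_in=len(set_a),
    )
    report["n_proximal_not_direct"] = (
        report["overlap"]["n_shared_a"] - report["summit_overlap"]["n_shared_a"]
    )
    report["enrichment"] = stage.run(
        "enrich",
        [config.peaks_a, config.peaks_b, config.chrom_sizes,
         config.n_perm, config.seed],
        lambda: permutation_enrichment(
            set_a, set_b, genome, n_perm=config.n_perm, seed=config.seed
        ).to_dict(),
        n_in=len(set_a),
    )

    def _targets():
        assignments, bound = assign_targets(
            set_a, annotation, max_dist=config.max_dist, mode=config.distance_mode
        )
        return {
            "n_bound_genes": len(bound),
            "bound_genes": sorted(bound),
            "assignments": [
                {"region": set_a[a.region_index].name or str(a.region_index),
                 "genes": [list(g) for g in a.genes]}
                for a in assignments
            ],
        }

    tgt = stage.run(
        "targets",
        [config.peaks_a, config.annotation, config.max_dist, config.distance_mode],
        _targets, n_in=len(set_a),
    )
    report["target_assignment"] = {"n_bound_genes": tgt["n_bound_genes"]}

    def _integrate():
        de = read_de_table(config.de_table)
        de_kept = filter_de(de, min_fc=config.min_fc, max_adj_p=config.max_adj_p)
        table = direct_targets(tgt["bound_genes"], de_kept)
        pct_down, pct_up = (
            direction_fractions(table) if table.n_total else (None, None)
        )
        return {
            "n_de_input": len(de),
            "n_de_filtered": len(de_kept),
            "n_direct_targets": table.n_total,
            "n_down": table.n_down,
            "n_up": table.n_up,
            "pct_down": pct_down,
            "pct_up": pct_up,
            "venn": {
                "bound_only": table.n_bound_only,
                "de_only": table.n_de_only,
                "shared": table.n_total,
            },
            "genes": {g: d for g, d, _ in table.rows},
        }

    integ = stage.run(
        "integrate",
        [config.peaks_a, config.annotation, config.de_table,
         config.min_fc, config.max_adj_p, config.max_dist, config.distance_mode],
        _integrate, n_in=tgt["n_bound_genes"],
    )
    report["direct_targets"] = integ

    if config.categories is not None:
        def _categories():
            de = read_de_table(config.de_table)
            de_kept = filter_de(de, min_fc=config.min_fc, max_adj_p=config.max_adj_p)
            table = direct_targets(tgt["bound_genes"], de_kept)
            df = category_direction_analysis(table, read_category_map(config.categories))
            return df.to_dict(orient="records")

        report["categories"] = stage.run(
            "categories",
            [config.peaks_a, config.annotation, config.de_table, config.categories,
             config.min_fc, config.max_adj_p, config.max_dist, config.distance_mode],
            _categories, n_in=integ["n_direct_targets"],
        )
    else:
        log.warning("no category map supplied; category analysis skipped")

    report_json = json.dumps(report, indent=1, sort_keys=True)
    (out_dir / "report.json").write_text(report_json + "\n")
    with open(out_dir / "report.tsv", "w") as fh:
        for key, value in sorted(_flatten(report).items()):
            fh.write(f"{key}\t{value}\n")
    return report


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, list):
            out[key] = json.dumps(v)
        else:
            out[key] = v
    return out
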