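"""End-to-end orchestration: simulate -> classify -> integrate -> correlate.

A single PipelineConfig (mirroring the CLI flags, loadable from YAML)
drives every stage; all randomness flows from its seeds, so a rerun with
the same config is byte-identical.  A manifest with the tool version, a
hash of the resolved config and per-stage row counts is always written,
even when a stage fails (partial, with the error recorded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .annotation import (
    annotate_peaks,
    load_gene_models,
    load_peaks,
    region_composition,
    tss_profile,
    write_annotations,
    write_composition,
    write_profile,
)
from .classify import (
    classify_peaks,
    filter_degs,
    intersect_targets,
    load_de_table,
    promoter_motif_search,
    summarize,
    write_classifications,
    write_targets,
)
from .motifs import default_motif_sets
from .tma import dichotomize, kendall_tau_b, load_scores, write_correlation, write_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and tunables for a full run; None paths skip their stage."""

    genome: str | None = None
    peaks: str | None = None
    genes: str | None = None
    de: str | None = None
    scores: str | None = None
    out: str = "cicscan_out"
    peak_format: str = "narrowPeak"
    gene_format: str = "GTF"
    q_threshold: float | None = None
    promoter_window: tuple[int, int] = (-2000, 200)
    downstream_extent: int = 3000
    min_repeat_units: int = 2
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.2
    both_strands: bool = False
    all_genes: bool = False
    p_method: str = "normal_approx"
    n_permutations: int = 100_000
    seed: int = 0

    def validate(self, require: tuple[str, ...] = ()) -> None:
        for name in require:
            path = getattr(self, name)
            if path is None:
                raise ConfigError(f"config is missing required path {name!r}")
            if not os.path.exists(path):
                raise ConfigError(f"{name} path does not exist: {path}")
        lo, hi = self.promoter_window
        if lo >= hi:
            raise ConfigError(f"promoter_window {self.promoter_window} is empty")
        if self.min_repeat_units < 1:
            raise ConfigError("min_repeat_units must be >= 1")
        if not (self.fc_threshold >= 0 and 0 <= self.fdr_threshold <= 1):
            raise ConfigError("DE thresholds out of range")
        if self.q_threshold is not None and not 0 < self.q_threshold <= 1:
            raise ConfigError("q_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.promoter_window, list):
            cfg.promoter_window = tuple(cfg.promoter_window)
        return cfg

    def digest(self) -> str:
        # hash the analytic parameters only, not the output location
        d = dataclasses.asdict(self)
        d.pop("out", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_genome(path: str) -> dict[str, str]:
    import pyfaidx

    fa = pyfaidx.Fasta(path)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary.

    Stage outputs land under ``config.out``; the manifest is written there
    as manifest.json in all cases (with an error record on failure).
    """
    os.makedirs(config.out, exist_ok=True)
    manifest: dict = {
        "tool": "cicscan",
        "version": __version__,
        "config_hash": config.digest(),
        "stages": {},
    }
    current = "config"
    try:
        config.validate(require=tuple(
            n for n in ("genome", "peaks", "genes", "de", "scores")
            if getattr(config, n) is not None
        ))
        if config.genome is None or config.peaks is None or config.genes is None:
            raise ConfigError("run requires genome, peaks and genes paths")

        current = "load"
        genome = _load_genome(config.genome)
        peaks = load_peaks(config.peaks, config.peak_format, config.q_threshold)
        genes = load_gene_models(config.genes, config.gene_format)
        manifest["stages"]["load"] = {
            "chromosomes": len(genome), "peaks": len(peaks), "genes": len(genes),
        }

        current = "annotate"
        anns = annotate_peaks(peaks, genes, config.promoter_window, config.downstream_extent)
        write_annotations(anns, os.path.join(config.out, "annotations.tsv"))
        if anns:
            write_composition(region_composition(anns), os.path.join(config.out, "composition.tsv"))
        profile = tss_profile(peaks, genes)
        write_profile(profile, os.path.join(config.out, "tss_profile.tsv"))
        manifest["stages"]["annotate"] = {
            "annotations": len(anns), "profile_peaks": profile.total,
        }

        current = "classify"
        motif_sets = default_motif_sets(config.min_repeat_units)
        cls = classify_peaks(peaks, genome, motif_sets, config.both_strands)
        write_classifications(cls, os.path.join(config.out, "classifications.tsv"))
        summary = summarize(cls, anns)
        with open(os.path.join(config.out, "summary.json"), "w") as fh:
            fh.write(summary.to_json() + "\n")
        manifest["stages"]["classify"] = {
            "peaks": summary.n_peaks, "counts": summary.counts,
        }

        current = "integrate"
        if config.de is not None:
            motif_genes = promoter_motif_search(
                genes, genome, motif_sets, config.promoter_window,
                annotations=anns, all_genes=config.all_genes,
                both_strands=config.both_strands,
            )
            de = load_de_table(config.de)
            degs = filter_degs(de, config.fc_threshold, config.fdr_threshold)
            result = intersect_targets(motif_genes, degs, de)
            write_targets(result, os.path.join(config.out, "putative_targets.tsv"))
            manifest["stages"]["integrate"] = {
                "motif_genes": len(motif_genes), "deg_genes": len(degs),
                "putative_targets": len(result.putative_targets),
            }

        current = "tma"
        if config.scores is not None:
            scores = load_scores(config.scores)
            corr = kendall_tau_b(
                scores, p_method=config.p_method,
                n_permutations=config.n_permutations, seed=config.seed,
            )
            write_correlation(corr, os.path.join(config.out, "correlation.json"))
            write_table(dichotomize(scores), os.path.join(config.out, "dichotomized.tsv"))
            manifest["stages"]["tma"] = {"pairs": corr.n, "tau_b": corr.tau_b}
    except Exception as exc:
        manifest["error"] = {"stage": current, "message": str(exc)}
        _write_manifest(manifest, config.out)
        if isinstance(exc, (ConfigError,)):
            raise
        raise StageError(current, exc) from exc
    _write_manifest(manifest, config.out)
    _write_report(manifest, config.out)
    return manifest


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_report(manifest: dict, outdir: str) -> None:
    lines = [
        "# cicscan run report", "",
        f"- version: {manifest['version']}",
        f"- config hash: {manifest['config_hash']}", "",
    ]
    for stage, info in manifest["stages"].items():
        lines.append(f"## {stage}")
        for k, v in sorted(info.items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
    with open(os.path.join(outdir, "report.md"), "w") as fh:
        fh.write("\n".join(lines))
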