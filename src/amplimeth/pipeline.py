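"""End-to-end orchestration: extract -> call -> estimate -> compare -> report.

Consumes a panel (FASTA + TOML) and a sample sheet (TSV: sample, condition,
fastq_r1, fastq_r2), writes per-amplicon extract files, pattern count tables,
estimated distributions, per-CpG levels, cross-condition Venn tables and a
JSON manifest with counts at every filter stage. Re-running with identical
inputs reproduces every table byte for byte.
"""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .compare import region_label, venn_counts
from .estimate import ErrorModel, PatternDistribution, apply_cutoff, estimate_distribution
from .estimate import write_distribution_tsv
from .extract import extract_pairs, write_extract_tsv
from .panel import load_panel
from .patterns import call_pattern, per_cpg_levels, tabulate_patterns, write_counts_tsv

logger = logging.getLogger("amplimeth")

__all__ = ["RunConfig", "SampleEntry", "read_sample_sheet", "run_pipeline"]


@dataclass(frozen=True)
class SampleEntry:
    sample: str
    condition: str
    fastq_r1: Path
    fastq_r2: Path


def read_sample_sheet(path: str | Path) -> list[SampleEntry]:
    """TSV with header sample/condition/fastq_r1/fastq_r2; paths are resolved
    relative to the sheet's directory."""
    path = Path(path)
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {k: i for i, k in enumerate(header)}
        for key in ("sample", "condition", "fastq_r1", "fastq_r2"):
            if key not in idx:
                raise ValueError(f"sample sheet missing column '{key}'")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            entries.append(
                SampleEntry(
                    sample=f[idx["sample"]],
                    condition=f[idx["condition"]],
                    fastq_r1=(path.parent / f[idx["fastq_r1"]]).resolve(),
                    fastq_r2=(path.parent / f[idx["fastq_r2"]]).resolve(),
                )
            )
    if not entries:
        raise ValueError(f"sample sheet {path} lists no samples")
    return entries


def _resolve_panel(panel_config: str | Path, template_fasta: str | Path | None):
    """Panel TOML may carry a top-level ``fasta`` key pointing at the templates."""
    panel_config = Path(panel_config)
    if template_fasta is None:
        with open(panel_config, "rb") as fh:
            cfg = tomllib.load(fh)
        if "fasta" not in cfg:
            raise ValueError(
                f"{panel_config}: no template FASTA given and no 'fasta' key in config"
            )
        template_fasta = panel_config.parent / cfg["fasta"]
    return load_panel(template_fasta, panel_config)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; validated before any work starts."""

    panel_config: Path
    sample_sheet: Path
    out_dir: Path
    template_fasta: Path | None = None
    error_model: ErrorModel = field(default_factory=ErrorModel.default)
    cutoffs: tuple[float, ...] = (0.01, 0.05)
    support_cut: float | None = None
    seed: int = 0
    figures: bool = False
    banded: bool = True

    def __post_init__(self) -> None:
        self.panel_config = Path(self.panel_config)
        self.sample_sheet = Path(self.sample_sheet)
        self.out_dir = Path(self.out_dir)
        for c in self.cutoffs:
            if not 0.0 <= c < 1.0:
                raise ValueError(f"cutoff {c} outside [0, 1)")
        for p in (self.panel_config, self.sample_sheet):
            if not p.exists():
                raise FileNotFoundError(p)


def _stage(name: str, context: str):
    """Log a stage; failures abort with the stage name and input context."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: %s", name, context)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage '{name}' failed for {context}: {exc}") from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "extracts").mkdir(exist_ok=True)

    with _stage("load_panel", str(config.panel_config)):
        panel = _resolve_panel(config.panel_config, config.template_fasta)
    with _stage("read_samples", str(config.sample_sheet)):
        samples = read_sample_sheet(config.sample_sheet)
    conditions: dict[str, list[str]] = {}
    for s in samples:
        conditions.setdefault(s.condition, []).append(s.sample)

    manifest: dict = {
        "tool": "amplimeth",
        "version": __version__,
        "seed": config.seed,
        "error_model": vars(config.error_model).copy(),
        "cutoffs": list(config.cutoffs),
        "support_cut": config.support_cut,
        "amplicons": {t.name: {"length_bp": t.length_bp, "n_cpgs": t.n_cpgs} for t in panel},
        "samples": {},
        "conservation_ok": True,
    }

    tables = []
    dists: list[PatternDistribution] = []
    by_amp_cond: dict[str, dict[str, PatternDistribution]] = {t.name: {} for t in panel}

    for s in samples:
        with _stage("extract", f"sample {s.sample}"):
            passed, stats = extract_pairs(s.fastq_r1, s.fastq_r2, panel, banded=config.banded)
        entry = stats.as_dict()
        entry["condition"] = s.condition
        entry["conservation_ok"] = stats.conservation_holds()
        manifest["conservation_ok"] &= entry["conservation_ok"]
        entry["calls"] = {}
        for t in panel:
            merged = passed[t.name]
            write_extract_tsv(merged, out / "extracts" / f"{s.sample}.{t.name}.tsv")
            with _stage("call", f"sample {s.sample}, amplicon {t.name}"):
                calls = [call_pattern(m, t, banded=config.banded) for m in merged]
                table = tabulate_patterns(calls, t.name, s.sample)
            entry["calls"][t.name] = {
                "n_merged": len(merged),
                "n_called": table.n_called,
                "n_ambiguous": table.n_ambiguous,
            }
            ok = table.n_called + table.n_ambiguous == len(merged)
            manifest["conservation_ok"] &= ok
            if not table.counts:
                logger.warning("no called patterns for %s/%s", s.sample, t.name)
                continue
            tables.append(table)
            with _stage("estimate", f"sample {s.sample}, amplicon {t.name}"):
                dist = estimate_distribution(
                    table, config.error_model, support_cut=config.support_cut
                )
            dists.append(dist)
            by_amp_cond[t.name].setdefault(s.condition, []).append(dist)
        manifest["samples"][s.sample] = entry

    write_counts_tsv(tables, out / "pattern_counts.tsv")
    write_distribution_tsv(dists, out / "distributions.tsv")
    if any(t.snp_calls for t in tables):
        with open(out / "snp_calls.tsv", "w") as fh:
            fh.write("amplicon\tsample\tpattern\tsnp_bases\tcount\n")
            for t in tables:
                for (pattern, snp), count in sorted((t.snp_calls or {}).items()):
                    fh.write(f"{t.amplicon}\t{t.sample}\t{pattern}\t{snp}\t{count}\n")
    with open(out / "estimation_log.tsv", "w") as fh:
        fh.write(
            "amplicon\tsample\tn_reads\tn_observed\tn_retained\tn_iter\t"
            "converged\tlog_likelihood\tsupport_cut\n"
        )
        for d in dists:
            fh.write(
                f"{d.amplicon}\t{d.sample}\t{d.n_reads}\t{len(d.observed_counts)}\t"
                f"{len(d.freqs)}\t{d.n_iter}\t{d.converged}\t"
                f"{d.log_likelihood:.6f}\t{d.support_cut:.3g}\n"
            )
    with open(out / "call_summary.tsv", "w") as fh:
        fh.write("amplicon\tsample\tcondition\tn_merged\tn_called\tn_ambiguous\n")
        for s in samples:
            entry = manifest["samples"][s.sample]
            for amp, c in entry["calls"].items():
                fh.write(
                    f"{amp}\t{s.sample}\t{s.condition}\t{c['n_merged']}\t"
                    f"{c['n_called']}\t{c['n_ambiguous']}\n"
                )
    with open(out / "per_cpg_levels.tsv", "w") as fh:
        fh.write("amplicon\tsample\tcpg_index\tlevel\n")
        for d in dists:
            for i, level in enumerate(per_cpg_levels(d), start=1):
                fh.write(f"{d.amplicon}\t{d.sample}\t{i}\t{level:.6f}\n")

    # cross-condition Venn tables, one per amplicon x cutoff, over <=5 conditions
    cond_order = list(conditions)
    for cutoff in config.cutoffs:
        pct = f"{cutoff:g}"
        with open(out / f"venn_cutoff{pct}.tsv", "w") as fh:
            fh.write("amplicon\tregion\tcount\n")
            for t in panel:
                sets = {}
                for cond in cond_order:
                    members = by_amp_cond[t.name].get(cond)
                    if not members:
                        continue
                    retained: set[str] = set()
                    for d in members:
                        retained |= apply_cutoff(d, cutoff)[1]
                    sets[cond] = retained
                if not 2 <= len(sets) <= 5:
                    logger.warning(
                        "amplicon %s: %d conditions, Venn needs 2-5; skipped",
                        t.name,
                        len(sets),
                    )
                    continue
                regions = venn_counts(sets)
                for subset, count in sorted(
                    regions.items(), key=lambda kv: (len(kv[0]), region_label(kv[0], cond_order))
                ):
                    fh.write(f"{t.name}\t{region_label(subset, cond_order)}\t{count}\n")

    if config.figures:
        from .report import render_reports

        with _stage("report", str(out)):
            render_reports(out)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return manifest


def configure_logging(verbose: int) -> None:
    level = logging.WARNING if verbose == 0 else logging.INFO if verbose == 1 else logging.DEBUG
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
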