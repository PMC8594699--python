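"""Figure export: pattern heat-grids with per-CpG level panels, Venn diagrams.

Every number a figure shows is read back from a table the pipeline exported
(distributions.tsv, call_summary.tsv, venn_cutoff*.tsv); nothing is recomputed
in plotting code, so figures can be regenerated from tables alone and always
agree with them. Output is deterministic SVG + PNG.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "amplimeth"  # deterministic SVG ids

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

logger = logging.getLogger("amplimeth")

__all__ = ["pattern_grid_figure", "venn_figure", "render_reports"]

_CMAP = matplotlib.colors.ListedColormap(["#f5f5f5", "#1a3f6b"])  # 0 / 1


def _save(fig, out_prefix: Path) -> list[Path]:
    paths = []
    for ext in ("svg", "png"):
        p = Path(f"{out_prefix}.{ext}")  # prefix may contain dots (cutoff0.01)
        fig.savefig(p, dpi=150, metadata={"Date": None} if ext == "svg" else None)
        paths.append(p)
    plt.close(fig)
    return paths


def pattern_grid_figure(
    patterns: list[str],
    freqs: list[float],
    levels: list[float],
    n_reads: int,
    title: str,
    out_prefix: str | Path,
) -> list[Path]:
    """Heat grid of patterns (rows, most frequent on top; columns = CpG index)
    over a lower panel of per-CpG combined levels; read count annotated."""
    n_cpg = len(patterns[0])
    bits = np.array([[int(c) for c in p] for p in patterns])
    fig, (ax, axl) = plt.subplots(
        2,
        1,
        figsize=(max(4, 0.45 * n_cpg + 1.5), max(3, 0.28 * len(patterns) + 2.2)),
        height_ratios=[max(len(patterns), 3), 3],
        sharex=True,
    )
    ax.imshow(bits, cmap=_CMAP, aspect="auto", vmin=0, vmax=1, interpolation="nearest")
    for i, f in enumerate(freqs):
        ax.text(n_cpg - 0.35, i, f"{f:.3f}", va="center", fontsize=7)
    ax.set_yticks(range(len(patterns)))
    ax.set_yticklabels([], fontsize=6)
    ax.set_ylabel("pattern (frequency ↓)")
    ax.set_title(title, fontsize=10)
    axl.bar(range(n_cpg), levels, color="#1a3f6b", width=0.8)
    axl.set_ylim(0, 1)
    axl.set_xticks(range(n_cpg))
    axl.set_xticklabels([str(i + 1) for i in range(n_cpg)], fontsize=7)
    axl.set_xlabel(f"CpG index    (n = {n_reads} reads)")
    axl.set_ylabel("level")
    fig.tight_layout()
    return _save(fig, Path(out_prefix))


def venn_figure(
    regions: dict[str, int],
    conditions: list[str],
    title: str,
    out_prefix: str | Path,
) -> list[Path]:
    """2-3-way comparisons as circle diagrams, 4-5-way as region bar charts.

    ``regions`` maps '&'-joined condition labels to exclusive pattern counts.
    """
    k = len(conditions)
    out_prefix = Path(out_prefix)
    if k == 2:
        a, b = conditions
        fig, ax = plt.subplots(figsize=(5, 4))
        for x, color in ((-0.55, "#c23b3b"), (0.55, "#2b6cb0")):
            ax.add_patch(plt.Circle((x, 0), 1.0, alpha=0.45, color=color))
        ax.text(-1.05, 0, str(regions.get(a, 0)), ha="center", fontsize=14)
        ax.text(1.05, 0, str(regions.get(b, 0)), ha="center", fontsize=14)
        ax.text(0, 0, str(regions.get(f"{a}&{b}", 0)), ha="center", fontsize=14)
        ax.text(-0.85, 1.15, a, ha="center", fontsize=10)
        ax.text(0.85, 1.15, b, ha="center", fontsize=10)
        ax.set_xlim(-2, 2)
        ax.set_ylim(-1.5, 1.6)
        ax.set_aspect("equal")
        ax.axis("off")
    elif k == 3:
        a, b, c = conditions
        centers = {a: (-0.5, 0.35), b: (0.5, 0.35), c: (0.0, -0.55)}
        colors = ["#c23b3b", "#2b6cb0", "#2f855a"]
        fig, ax = plt.subplots(figsize=(5, 5))
        for (cond, (x, y)), color in zip(centers.items(), colors):
            ax.add_patch(plt.Circle((x, y), 1.0, alpha=0.4, color=color))
            ax.text(x * 1.9, y * 1.9 + (0.25 if y > 0 else -0.2), cond, ha="center", fontsize=9)
        text_pos = {
            a: (-1.0, 0.6),
            b: (1.0, 0.6),
            c: (0.0, -1.15),
            f"{a}&{b}": (0.0, 0.7),
            f"{a}&{c}": (-0.62, -0.35),
            f"{b}&{c}": (0.62, -0.35),
            f"{a}&{b}&{c}": (0.0, 0.05),
        }
        for label, (x, y) in text_pos.items():
            ax.text(x, y, str(regions.get(label, 0)), ha="center", fontsize=12)
        ax.set_xlim(-2.2, 2.2)
        ax.set_ylim(-2.1, 2.0)
        ax.set_aspect("equal")
        ax.axis("off")
    else:
        labels = sorted(regions, key=lambda r: (r.count("&"), r))
        values = [regions[r] for r in labels]
        fig, ax = plt.subplots(figsize=(6, 0.3 * len(labels) + 1.5))
        ax.barh(range(len(labels)), values, color="#2b6cb0")
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels(labels, fontsize=7)
        ax.invert_yaxis()
        ax.set_xlabel("exclusive patterns")
        for i, v in enumerate(values):
            ax.text(v, i, f" {v}", va="center", fontsize=7)
    fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    return _save(fig, out_prefix)


def render_reports(run_dir: str | Path) -> list[Path]:
    """Regenerate all figures of a pipeline run from its exported tables."""
    run_dir = Path(run_dir)
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    written: list[Path] = []

    dist_path = run_dir / "distributions.tsv"
    summary_path = run_dir / "call_summary.tsv"
    if not dist_path.exists() or dist_path.stat().st_size == 0:
        logger.warning("no distributions table in %s; no figures rendered", run_dir)
        return written
    dist = pd.read_csv(dist_path, sep="\t", dtype={"pattern": str})
    if dist.empty:
        logger.warning("empty distributions table in %s; no figures rendered", run_dir)
        return written
    summary = pd.read_csv(summary_path, sep="\t")
    levels = pd.read_csv(run_dir / "per_cpg_levels.tsv", sep="\t")

    for (amp, sample), grp in dist.groupby(["amplicon", "sample"], sort=True):
        grp = grp.sort_values(["est_frequency", "pattern"], ascending=[False, True])
        row = summary[(summary.amplicon == amp) & (summary["sample"] == sample)]
        n_reads = int(row.n_called.iloc[0]) if len(row) else 0
        lv = levels[(levels.amplicon == amp) & (levels["sample"] == sample)].sort_values(
            "cpg_index"
        )
        written += pattern_grid_figure(
            list(grp.pattern),
            list(grp.est_frequency),
            list(lv.level),
            n_reads,
            f"{amp} / {sample}",
            fig_dir / f"patterns_{amp}_{sample}",
        )

    for venn_path in sorted(run_dir.glob("venn_cutoff*.tsv")):
        vt = pd.read_csv(venn_path, sep="\t")
        cutoff = venn_path.stem.replace("venn_cutoff", "")
        for amp, grp in vt.groupby("amplicon", sort=True):
            conditions: list[str] = []
            for region in grp.region:
                for cond in str(region).split("&"):
                    if cond not in conditions:
                        conditions.append(cond)
            regions = {str(r): int(c) for r, c in zip(grp.region, grp["count"])}
            written += venn_figure(
                regions,
                conditions,
                f"{amp}, cutoff {cutoff}",
                fig_dir / f"venn_{amp}_cutoff{cutoff}",
            )
    return written
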