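"""Publication-style figures from a measurement table (vector output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .popstats import MEASUREMENT_COLUMNS, UNITS

SECTOR_COLORS = {
    "suprapyramidal": "#1f77b4",
    "crest": "#2ca02c",
    "infrapyramidal": "#d62728",
}


def _beeswarm(ax, table, col):
    rng = np.random.default_rng(0)
    for i, (sector, color) in enumerate(SECTOR_COLORS.items()):
        vals = table.loc[table["sector"] == sector, col].dropna().to_numpy()
        if len(vals) == 0:
            continue
        x = i + rng.uniform(-0.18, 0.18, size=len(vals))
        ax.plot(x, vals, "o", ms=2.5, alpha=0.6, color=color)
        ax.hlines(np.median(vals), i + 0.25, i + 0.4, color="k", lw=2)
    ax.set_xticks(range(len(SECTOR_COLORS)))
    ax.set_xticklabels([s[:5] for s in SECTOR_COLORS], fontsize=7)
    unit = UNITS.get(col, "")
    ax.set_title(f"{col}" + (f" ({unit})" if unit else ""), fontsize=8)


def beeswarm_panels(table, path: Path, columns=None):
    cols = [c for c in (columns or MEASUREMENT_COLUMNS) if c in table.columns]
    n = len(cols)
    ncol = 6
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.1 * ncol, 2.2 * nrow))
    for ax, col in zip(np.ravel(axes), cols):
        _beeswarm(ax, table, col)
    for ax in np.ravel(axes)[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def fi_summary(table, path: Path):
    fig, ax = plt.subplots(figsize=(4, 3))
    amps = [50, 100, 150, 200, 250]
    for sector, color in SECTOR_COLORS.items():
        sub = table[table["sector"] == sector]
        means = [sub[f"f_{a}"].mean() for a in amps]
        ses = [sub[f"f_{a}"].std() / np.sqrt(sub[f"f_{a}"].notna().sum()) for a in amps]
        ax.errorbar(amps, means, yerr=ses, marker="o", ms=4, label=sector, color=color)
    ax.set_xlabel("injected current (pA)")
    ax.set_ylabel("firing rate (Hz)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def correlation_figure(corr, path: Path):
    R = corr.R.to_numpy()
    fig, (ax, axh) = plt.subplots(
        1, 2, figsize=(8, 3.6), gridspec_kw={"width_ratios": [1.4, 1]}
    )
    im = ax.imshow(R, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.R)))
    ax.set_xticklabels(corr.R.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.R)))
    ax.set_yticklabels(corr.R.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson R")
    axh.hist(corr.r_values, bins=np.arange(-1, 1.05, 0.1), color="gray")
    axh.axvline(-0.4, color="k", ls="--", lw=1)
    axh.axvline(0.4, color="k", ls="--", lw=1)
    axh.set_xlabel("pairwise R")
    axh.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pca_figure(pca, path: Path):
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    pairs = [("PC1", "PC2"), ("PC2", "PC3"), ("PC3", "PC1")]
    for ax, (a, b) in zip(axes, pairs):
        for sector, color in SECTOR_COLORS.items():
            sub = pca.scores[pca.scores["sector"] == sector]
            ax.plot(sub[a], sub[b], "o", ms=3, alpha=0.6, color=color, label=sector)
        ia, ib = int(a[2]) - 1, int(b[2]) - 1
        ax.set_xlabel(f"{a} ({pca.explained_fraction[ia]*100:.0f}%)")
        ax.set_ylabel(f"{b} ({pca.explained_fraction[ib]*100:.0f}%)")
    axes[0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def standard_figures(table, stats: dict, outdir: Path):
    outdir = Path(outdir)
    beeswarm_panels(table, outdir / "measurements_beeswarm.svg")
    fi_summary(table, outdir / "fi_curves.svg")
    if stats.get("correlation") is not None:
        correlation_figure(stats["correlation"], outdir / "correlations.svg")
    if stats.get("pca") is not None:
        pca_figure(stats["pca"], outdir / "pca.svg")
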