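"""Optional figure outputs: volcano, actual-vs-predicted, VIP, density maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import tifffile

from .workflows import DifferentialTable, PlsReport


def volcano_plot(table: DifferentialTable, path: str | Path,
                 effect_cutoff: float = 1.0) -> None:
    t = table.table.replace([np.inf, -np.inf], np.nan).dropna(subset=["effect"])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(t["effect"], -np.log10(t["p"]), s=12)
    for cut in (0.05, 0.10):
        ax.axhline(-np.log10(cut), ls="--", lw=0.8, color="grey")
    ax.axvline(effect_cutoff, ls="--", lw=0.8, color="grey")
    ax.axvline(-effect_cutoff, ls="--", lw=0.8, color="grey")
    ax.set_xlabel(f"log2({table.group_a} / {table.group_b})")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def actual_vs_predicted_plot(report: PlsReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(report.predicted, report.actual, s=14)
    lo = min(report.actual.min(), report.predicted.min())
    hi = max(report.actual.max(), report.predicted.max())
    ax.plot([lo, hi], [lo, hi], lw=0.8, color="grey")
    q2 = report.cv.q2[report.a_star - 1]
    ax.set_title(f"{report.y_name}: A*={report.a_star}, Q2={q2:.3f}")
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def vip_coefficient_plot(report: PlsReport, path: str | Path) -> None:
    t = report.vip_table
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(t["coef"], t["vip"], s=14)
    ax.axhline(1.0, ls="--", lw=0.8, color="grey")
    ax.axvline(0.0, ls="--", lw=0.8, color="grey")
    for name, row in t.iterrows():
        if row["vip"] > 1.0:
            ax.annotate(name, (row["coef"], row["vip"]), fontsize=7)
    ax.set_xlabel("model coefficient (standardized)")
    ax.set_ylabel("VIP")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_density_map(density: np.ndarray, path: str | Path,
                     png_preview: str | Path | None = None) -> None:
    tifffile.imwrite(str(path), density.astype(np.float32))
    if png_preview is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(density, cmap="magma")
        ax.axis("off")
        fig.savefig(png_preview, dpi=150, bbox_inches="tight")
        plt.close(fig)
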