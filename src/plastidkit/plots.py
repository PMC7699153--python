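"""SVG figure output for the four standard codon-bias/divergence plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bias import EncCurvePoint, PR2Point
from .codon import enc_expected
from .diversity import WindowDiversity

__all__ = ["plot_enc_gc3s", "plot_pr2", "plot_neutrality", "plot_window_pi"]


def plot_enc_gc3s(points: list[EncCurvePoint], path: str | Path) -> None:
    """ENc against GC3s per gene, with Wright's mutation-drift curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    s = np.linspace(0.0, 1.0, 200)
    ax.plot(s, [enc_expected(x) for x in s], "k--", lw=1,
            label="expected (mutation only)")
    ax.scatter([p.gc3s for p in points], [p.enc_observed for p in points],
               s=12, alpha=0.7)
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENc")
    ax.set_ylim(15, 65)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_pr2(points: list[PR2Point], path: str | Path) -> None:
    """PR2 plane: AT-bias vs GC-bias with the (0.5, 0.5) no-bias cross."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    for p in points:
        ax.scatter(p.gc_bias, p.at_bias, s=20)
        ax.annotate(p.label, (p.gc_bias, p.at_bias), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("G3s / (G3s + C3s)")
    ax.set_ylabel("A3s / (A3s + T3s)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_neutrality(points: list[tuple[float, float]], slope: float,
                    intercept: float, path: str | Path) -> None:
    """GC12 against GC3 per gene with the fitted regression line."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    gc3 = [p[1] for p in points]
    ax.scatter(gc3, [p[0] for p in points], s=12, alpha=0.7)
    xs = np.linspace(min(gc3), max(gc3), 2)
    ax.plot(xs, slope * xs + intercept, "r-", lw=1,
            label=f"slope {slope:.3f}")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_window_pi(windows: list[WindowDiversity], threshold: float,
                   path: str | Path) -> None:
    """π along the genome with the hotspot threshold line."""
    fig, ax = plt.subplots(figsize=(8, 3))
    xs = [(w.start + w.end) / 2 for w in windows if w.pi is not None]
    ys = [w.pi for w in windows if w.pi is not None]
    ax.plot(xs, ys, lw=0.8)
    ax.axhline(threshold, color="r", lw=0.8, ls="--")
    ax.set_xlabel("alignment position (bp)")
    ax.set_ylabel("pi")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
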