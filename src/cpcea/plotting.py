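"""Matplotlib views of the PSA outputs (CEACs, ellipses, CE plane)."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .uncertainty import CeacCurve, EllipsePath, PsaDraws


def plot_ceac(curves: Sequence[CeacCurve], path=None, ax=None):
    """Acceptability curves, one line per therapy/strategy."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for curve in curves:
        ax.plot(curve.wtp_grid, curve.probabilities, label=curve.label)
    ax.set_xlabel("Willingness to pay (EUR/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_ellipses(ellipses: Iterable[EllipsePath], path=None, ax=None, label=None):
    """Nested confidence ellipses on the cost-effectiveness plane."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    for e in ellipses:
        ax.plot(e.boundary[:, 1], e.boundary[:, 0], label=f"{e.level:.0%}")
        ax.plot(e.center[1], e.center[0], "k+")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental effect (QALY)")
    ax.set_ylabel("Incremental cost (EUR)")
    if label:
        ax.set_title(label)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_ce_plane(draws: PsaDraws, path=None, ax=None, wtp: float | None = None):
    """Scatter of PSA draws on the cost-effectiveness plane."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    ax.scatter(draws.draws[:, 1], draws.draws[:, 0], s=6, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    if wtp is not None:
        xs = ax.get_xlim()
        ax.plot(xs, [wtp * x for x in xs], "r--", lw=0.8, label=f"WTP {wtp:,.0f}")
        ax.legend(fontsize=8)
    ax.set_xlabel("Incremental effect (QALY)")
    ax.set_ylabel("Incremental cost (EUR)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
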