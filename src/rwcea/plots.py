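"""Figures for the economic evaluation: CE plane, CEAC, INMB curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .econ import CEResult

_EFFECT_NAMES = {"ly": "life-years", "qaly": "QALYs"}


def ce_plane(result: CEResult, path: str | Path, wtp_line: float = 50_000.0) -> None:
    """Scatter of bootstrap (dE, dC) pairs with the WTP threshold line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        result.draws["delta_effect"], result.draws["delta_cost"],
        s=6, alpha=0.4, edgecolors="none",
    )
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    xs = ax.get_xlim()
    ax.plot(xs, [wtp_line * x for x in xs], "--", color="grey", lw=0.8,
            label=f"WTP ${wtp_line:,.0f}")
    ax.plot([result.delta_effect], [result.delta_cost], "r*", ms=10,
            label="point estimate")
    ax.set_xlabel(f"incremental {_EFFECT_NAMES[result.effect_label]}")
    ax.set_ylabel("incremental cost ($)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_curve(result: CEResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.ceac["wtp"], result.ceac["probability"], marker="o", ms=3)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel(f"willingness to pay ($ per {_EFFECT_NAMES[result.effect_label]})")
    ax.set_ylabel("P(focal strategy cost-effective)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def inmb_curve(result: CEResult, path: str | Path) -> None:
    g = result.inmb_grid
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(g["wtp"], g["inmb"], color="C0")
    ax.fill_between(g["wtp"], g["ci_low"], g["ci_high"], alpha=0.2, color="C0")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel(f"willingness to pay ($ per {_EFFECT_NAMES[result.effect_label]})")
    ax.set_ylabel("incremental net monetary benefit ($)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
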