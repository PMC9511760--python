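"""Standard figures: cost-effectiveness plane, CEAC, tornado diagram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .sensitivity import PSAResult, TornadoEntry, ceac


def ce_plane(psa: PSAResult, path, wtp: float | None = None) -> None:
    wtp = wtp or psa.wtp
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=4, alpha=0.3, edgecolors="none")
    lim = max(abs(psa.delta_qaly).max(), 0.1)
    xs = np.linspace(-lim, lim, 50)
    ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(psa: PSAResult, path, wtp_grid=None) -> None:
    grid = np.asarray(wtp_grid) if wtp_grid is not None else np.linspace(0, 3e4, 121)
    probs = ceac(psa, grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, probs)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tornado_plot(entries: list[TornadoEntry], base_icer: float, path, top: int = 15) -> None:
    entries = entries[:top][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base_icer, color="k", lw=1, ls="--")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.name for e in entries], fontsize=8)
    ax.set_xlabel("ICER (USD/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
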