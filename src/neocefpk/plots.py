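"""Diagnostic figures: goodness-of-fit panels, NPDE QQ/histogram, pcVPC ribbon."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy import stats

from ._engine import conditional_pieces, pack, solve_etas
from .diagnostics import NpdeResult, VpcResult, _fit_cl_v, cwres
from .estimate import FitResult
from .io import PKDataset

__all__ = ["gof_panels", "npde_panels", "vpc_plot"]


def gof_panels(fit: FitResult, data: PKDataset, path: str) -> None:
    """PRED vs DV, IPRED vs DV, CWRES vs PRED and CWRES vs time panels."""
    design = pack(data)
    cl, v = _fit_cl_v(fit, design)
    eta = solve_etas(design, cl, v, fit.omega2_cl, fit.omega2_v, fit.sigma2_prop)
    pieces = conditional_pieces(
        design, cl, v, fit.omega2_cl, fit.omega2_v, fit.sigma2_prop, eta
    )
    m = design.obs_mask
    dv = design.obs_y[m]
    pred = pieces["pred"][m]
    ipred = pieces["ipred"][m]
    res = cwres(fit, data)
    t = design.obs_t[m]

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, x, xlabel in ((axes[0, 0], pred, "PRED (mg/L)"), (axes[0, 1], ipred, "IPRED (mg/L)")):
        ax.plot(x, dv, "o", ms=4, alpha=0.7)
        lim = [0, max(dv.max(), x.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("DV (mg/L)")
    for ax, x, xlabel in ((axes[1, 0], pred, "PRED (mg/L)"), (axes[1, 1], t, "time (h)")):
        ax.plot(x, res, "o", ms=4, alpha=0.7)
        ax.axhline(0, color="k", lw=1, ls="--")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def npde_panels(result: NpdeResult, path: str) -> None:
    """QQ-plot against N(0,1) and histogram with the standard-normal density."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    stats.probplot(result.values, dist="norm", plot=ax1)
    ax1.set_title("NPDE QQ-plot")
    ax2.hist(result.values, bins=15, density=True, alpha=0.7)
    grid = np.linspace(-4, 4, 200)
    ax2.plot(grid, stats.norm.pdf(grid), "k-", lw=1.5)
    ax2.set_xlabel("NPDE")
    ax2.set_title(f"mean {result.mean:.3f}, var {result.variance:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def vpc_plot(result: VpcResult, path: str) -> None:
    """Prediction-corrected VPC: observed percentiles with simulation bands."""
    fig, ax = plt.subplots(figsize=(7, 5))
    x = result.bin_mid
    labels = ("5th", "median", "95th")
    styles = ("--", "-", "--")
    for i, (lab, st) in enumerate(zip(labels, styles)):
        ax.fill_between(x, result.envelope_lo[i], result.envelope_hi[i],
                        alpha=0.25, color="grey" if i != 1 else "steelblue")
        ax.plot(x, result.observed[i], st, color="k", label=f"observed {lab}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
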