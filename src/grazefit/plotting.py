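"""Static diagnostic figures for fitted responses.

Pointwise 95% confidence bands are delta-method (linearized) bands
around the fitted curve; they describe uncertainty of the mean curve,
not prediction intervals for new wells.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .fitting import FitResult

__all__ = ["plot_response"]


def _band(fit: FitResult, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Delta-method 95% band via finite-difference parameter gradients."""
    names = list(fit.params)
    se = np.array([fit.se.get(k, 0.0) for k in names])
    if not np.all(np.isfinite(se)):
        return None
    base = np.asarray(fit.predict(grid), dtype=float)
    grads = []
    for k in names:
        p0 = fit.params[k]
        step = abs(p0) * 1e-6 + 1e-12
        bumped = FitResult(
            model_id=fit.model_id,
            params={**fit.params, k: p0 + step},
            se=fit.se,
            pvalues=fit.pvalues,
            rss=fit.rss,
            n=fit.n,
            n_params=fit.n_params,
            aicc=fit.aicc,
        )
        grads.append((np.asarray(bumped.predict(grid)) - base) / step)
    # independent-parameter approximation: covariances not stored
    var = sum((g * s) ** 2 for g, s in zip(grads, se))
    half = 1.96 * np.sqrt(var)
    return base - half, base + half


def plot_response(
    density,
    response,
    fit: FitResult | None = None,
    ylabel: str = "rate",
    path=None,
):
    """Scatter the per-well data and overlay a fitted curve with bands."""
    density = np.asarray(density, dtype=float)
    response = np.asarray(response, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(density, response, "o", ms=5, color="k", mfc="none", label="wells")
    if fit is not None:
        grid = np.linspace(max(density.min(), 1.0), density.max(), 200)
        ax.plot(grid, fit.predict(grid), "-", color="C0", label=fit.model_id)
        band = _band(fit, grid)
        if band is not None:
            ax.plot(grid, band[0], "--", lw=0.8, color="C0")
            ax.plot(grid, band[1], "--", lw=0.8, color="C0")
    ax.set_xlabel("prey density (cells mL$^{-1}$)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
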