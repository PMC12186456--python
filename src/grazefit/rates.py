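"""Per-well rate estimation from incubation cell counts.

Turns raw well observations (initial/final prey and predator densities
over a known duration) into the derived quantities the response models
are fitted to:

* predator specific growth rate            r  = ln(Nt/N0)/t
* prey growth rate in controls             μ  = ln(Ct/C0)/t
* grazing coefficient                      g  = μ_control − ln(Pt/P0)/t
* logarithmic-mean density                 P̄  = (Pt−P0)/ln(Pt/P0)
* per-capita ingestion                     I  = P̄·g/Rm   (× m/1000 for ng C)
* clearance rate                           C  = I/P̄  (≡ proportion of a
                                              1-mL reference volume cleared)
* gross growth efficiency                  GGE = r·M/I_carbon

Because prey also changes in predator-free controls, g depends on a
control-derived μ; several assignment strategies (global mean, density
bins, nearest control, log-density interpolation) are provided, plus the
uncorrected variant μ ≡ 0 used when controls are not trusted.  Negative
grazing/ingestion values are retained and flagged, never clamped: both
the corrected and uncorrected datasets are legitimate analysis branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomass import (
    PREDATOR_CARBON,
    PREDATOR_CELL_VOLUME,
    PREY_CARBON,
    PREY_CELL_VOLUME,
    CarbonModel,
    carbon_from_volume,
)

__all__ = [
    "WellObservation",
    "UndefinedRateError",
    "MIN_COUNTED_CELLS",
    "specific_growth_rate",
    "log_mean_density",
    "grazing_rate",
    "assign_control_mu",
    "ingestion_rate",
    "clearance_and_proportion",
    "gross_growth_efficiency",
    "gross_growth_efficiency_volume",
    "generation_time",
    "control_mu_table",
    "derive_rates",
]

#: Counting-precision guideline: flag wells with fewer counted cells.
MIN_COUNTED_CELLS = 50


class UndefinedRateError(ValueError):
    """Raised when a rate is undefined (zero counts, zero duration...)."""


@dataclass(frozen=True)
class WellObservation:
    """One incubation container (a single well/bottle).

    Densities are cells mL⁻¹; counted_* are raw counted-cell numbers in
    the subsamples; predator fields must be ``None`` for controls.
    ``flw_fraction`` is the proportion of the container volume filled
    with filtered lake water (diluent), a bias covariate.
    """

    well_id: str
    role: str  # "experimental" | "control"
    P0: float
    Pt: float
    t_days: float
    R0: float | None = None
    Rt: float | None = None
    counted_prey_0: float | None = None
    counted_prey_t: float | None = None
    counted_pred_0: float | None = None
    counted_pred_t: float | None = None
    subsample_mL: float | None = None
    flw_fraction: float = 0.0
    target_prey: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("experimental", "control"):
            raise ValueError(f"role must be experimental|control, got {self.role!r}")
        if not self.t_days > 0:
            raise ValueError(f"duration must be > 0 d, got {self.t_days}")
        for name in ("P0", "Pt"):
            v = getattr(self, name)
            if v is None or v < 0:
                raise ValueError(f"{name} must be a non-negative density, got {v}")
        if not 0.0 <= self.flw_fraction <= 1.0:
            raise ValueError(f"flw_fraction must be in [0, 1], got {self.flw_fraction}")
        if self.role == "control":
            for name in ("R0", "Rt", "counted_pred_0", "counted_pred_t"):
                if getattr(self, name) is not None:
                    raise ValueError(
                        f"control well {self.well_id!r} must not carry predator "
                        f"field {name}"
                    )
        else:
            for name in ("R0", "Rt"):
                v = getattr(self, name)
                if v is None or v < 0:
                    raise ValueError(
                        f"experimental well {self.well_id!r} needs non-negative "
                        f"{name}, got {v}"
                    )


def specific_growth_rate(n0: float, nt: float, t: float) -> float:
    """Specific growth rate r = ln(nt/n0)/t (d⁻¹).

    Negative r is a valid decline; zero initial or final abundance makes
    the rate undefined and raises :class:`UndefinedRateError`.
    """
    if t <= 0:
        raise UndefinedRateError(f"duration must be > 0, got {t}")
    if n0 <= 0 or nt <= 0:
        raise UndefinedRateError(
            f"growth rate undefined for non-positive abundances ({n0}, {nt})"
        )
    return math.log(nt / n0) / t


def log_mean_density(x0: float, xt: float) -> float:
    """Logarithmic (geometric) mean density (Xt − X0)/ln(Xt/X0).

    The time-averaged density under exponential change; continuous limit
    X0 when Xt → X0.  Lies strictly between min and max of the inputs
    and is symmetric in them.
    """
    if x0 <= 0 or xt <= 0:
        raise UndefinedRateError(
            f"log-mean density undefined for non-positive inputs ({x0}, {xt})"
        )
    if math.isclose(x0, xt, rel_tol=1e-12):
        return (x0 + xt) / 2.0
    return (xt - x0) / math.log(xt / x0)


def grazing_rate(mu_control: float, p0: float, pt: float, t: float) -> float:
    """Grazing coefficient g = μ_control − ln(Pt/P0)/t (d⁻¹).

    With μ_control computed from a single control's (C0, Ct) this is
    algebraically (ln(Ct/C0) − ln(Pt/P0))/t.  Pass ``mu_control=0`` for
    the uncorrected variant.  Negative g is returned as-is (flagged by
    :func:`derive_rates`, not clamped).
    """
    return mu_control - specific_growth_rate(p0, pt, t)


def generation_time(r: float) -> float:
    """Population doubling (generation) time G = ln 2 / r (d) for r > 0."""
    if r <= 0:
        raise UndefinedRateError(f"generation time undefined for r <= 0 ({r})")
    return math.log(2.0) / r


def ingestion_rate(
    p_mean: float, g: float, rm: float, m_pg: float | None = None
) -> tuple[float, float | None]:
    """Per-capita ingestion I = P̄·g/Rm (prey predator⁻¹ d⁻¹).

    Returns ``(I_cells, I_carbon)`` with I_carbon = I_cells·m/1000 in
    ng C predator⁻¹ d⁻¹ when the per-cell prey carbon ``m_pg`` (pg C) is
    given, else ``(I_cells, None)``.  The sign of I follows g.
    """
    if p_mean <= 0:
        raise UndefinedRateError(f"mean prey density must be > 0, got {p_mean}")
    if rm <= 0:
        raise UndefinedRateError(f"mean predator density must be > 0, got {rm}")
    i_cells = p_mean * g / rm
    i_carbon = i_cells * m_pg / 1000.0 if m_pg is not None else None
    return i_cells, i_carbon


def clearance_and_proportion(i_cells: float, p: float) -> tuple[float, float]:
    """Clearance rate C = I/P (mL predator⁻¹ d⁻¹) and proportion ingested.

    The clearance rate numerically equals the fraction of prey in a 1-mL
    reference volume removed per day, so the second return value is the
    same number interpreted as a proportion (d⁻¹).
    """
    if p <= 0:
        raise UndefinedRateError(f"prey density must be > 0, got {p}")
    c = i_cells / p
    return c, c


def gross_growth_efficiency(r: float, m_pred_ng: float, i_carbon_ng: float) -> float:
    """Carbon-basis gross growth efficiency GGE = r·M/I_carbon.

    M is predator carbon per cell (ng C) and I_carbon the carbon
    ingestion rate (ng C predator⁻¹ d⁻¹, must be > 0).  Physically
    meaningful GGE lies in (0, 1); out-of-range values signal an
    inconsistency between the growth and feeding estimates.
    """
    if i_carbon_ng <= 0:
        raise UndefinedRateError(
            f"GGE undefined for non-positive ingestion ({i_carbon_ng})"
        )
    return r * m_pred_ng / i_carbon_ng


def gross_growth_efficiency_volume(
    r: float, v_pred_um3: float, i_cells: float, v_prey_um3: float
) -> float:
    """Volume-basis gross growth efficiency r·V_pred/(I·V_prey)."""
    if i_cells <= 0:
        raise UndefinedRateError(f"GGE undefined for non-positive ingestion ({i_cells})")
    if v_pred_um3 <= 0 or v_prey_um3 <= 0:
        raise ValueError("cell volumes must be > 0")
    return r * v_pred_um3 / (i_cells * v_prey_um3)


# ---------------------------------------------------------------------------
# control-to-well prey growth assignment


def control_mu_table(wells: list[WellObservation]) -> pd.DataFrame:
    """Per-control prey growth rates μ = ln(Pt/P0)/t as a tidy table."""
    rows = []
    for w in wells:
        if w.role != "control":
            continue
        rows.append(
            {
                "well_id": w.well_id,
                "target_prey": w.target_prey,
                "P0": w.P0,
                "Pt": w.Pt,
                "t_days": w.t_days,
                "mu": specific_growth_rate(w.P0, w.Pt, w.t_days),
                "flw_fraction": w.flw_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["well_id", "target_prey", "P0", "Pt", "t_days", "mu", "flw_fraction"],
    )


def assign_control_mu(
    controls: pd.DataFrame,
    query_density,
    strategy: str = "density_bins",
    n_bins: int = 3,
) -> tuple[np.ndarray, list[str]]:
    """Assign a control-derived prey growth rate μ to each experimental well.

    Parameters
    ----------
    controls : DataFrame
        Output of :func:`control_mu_table` (needs ``mu`` and ``P0``).
    query_density : array-like
        Initial prey density of each experimental well.
    strategy : {"global_mean", "density_bins", "nearest_control", "interpolate"}
        How control μ values are extrapolated across the density axis.
        ``density_bins`` (default) averages controls within ``n_bins``
        log-density bins and assigns each well its bin's mean — the
        pragmatic middle ground when per-density interpolation is too
        noisy.  ``interpolate`` is linear in ln(density).
    n_bins : int
        Number of log-density bins for ``density_bins``.

    Returns
    -------
    mu : ndarray
        One μ per query well.
    provenance : list of str
        Which controls contributed to each assignment.
    """
    q = np.asarray(query_density, dtype=float)
    if len(controls) == 0:
        raise UndefinedRateError(
            "no controls available; only the uncorrected variant (mu = 0) is possible"
        )
    cd = controls["P0"].to_numpy(dtype=float)
    cmu = controls["mu"].to_numpy(dtype=float)
    cid = controls["well_id"].astype(str).to_numpy()

    if strategy == "global_mean":
        mu = np.full_like(q, cmu.mean())
        prov = ["mean(" + ",".join(cid) + ")"] * len(q)
        return mu, prov

    if strategy == "nearest_control":
        idx = np.array(
            [int(np.argmin(np.abs(np.log(cd) - math.log(max(d, 1e-300))))) for d in q]
        )
        return cmu[idx], [cid[i] for i in idx]

    if strategy == "interpolate":
        order = np.argsort(cd)
        mu = np.interp(np.log(q), np.log(cd[order]), cmu[order])
        prov = ["loginterp(" + ",".join(cid[order]) + ")"] * len(q)
        return mu, prov

    if strategy == "density_bins":
        k = min(n_bins, len(controls))
        logd = np.log(cd)
        # equal-count (quantile) bins over the controls' log densities
        edges = np.quantile(logd, np.linspace(0, 1, k + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        cbin = np.clip(np.searchsorted(edges, logd, side="right") - 1, 0, k - 1)
        bin_mu = np.array([cmu[cbin == b].mean() for b in range(k)])
        bin_ids = [",".join(cid[cbin == b]) for b in range(k)]
        qbin = np.clip(np.searchsorted(edges, np.log(q), side="right") - 1, 0, k - 1)
        return bin_mu[qbin], [f"bin{b}({bin_ids[b]})" for b in qbin]

    raise ValueError(f"unknown control-mu strategy {strategy!r}")


# ---------------------------------------------------------------------------
# full per-well derivation


@dataclass
class RateOptions:
    """Knobs of :func:`derive_rates` collected in one place."""

    correction: str = "controls"  # "controls" | "none"
    mu_strategy: str = "density_bins"
    n_bins: int = 3
    rm_method: str = "logmean"  # "logmean" | "geometric"
    ingestion_density: str = "mean"  # "mean" | "initial": the P in I = P·g/Rm
    prey_cell_volume: float = PREY_CELL_VOLUME
    predator_cell_volume: float = PREDATOR_CELL_VOLUME
    prey_carbon: CarbonModel = PREY_CARBON
    predator_carbon: CarbonModel = PREDATOR_CARBON


def _mean_predator(r0: float, rt: float, method: str) -> float:
    if method == "geometric":
        return math.sqrt(r0 * rt)
    return log_mean_density(r0, rt)


def derive_rates(
    wells: list[WellObservation],
    options: RateOptions | None = None,
    **overrides,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the full rate table from well observations.

    Returns ``(rates, controls)``: one row per experimental well with
    r, μ assignments, g, P̄, Rm, I (cells and carbon), C, proportion
    ingested, GGE and quality flags; and the per-control μ table.
    Provenance (correction variant, density used in I, μ strategy) is
    stored in ``rates.attrs``.
    """
    opts = options or RateOptions()
    for k, v in overrides.items():
        if not hasattr(opts, k):
            raise TypeError(f"unknown rate option {k!r}")
        setattr(opts, k, v)
    if opts.correction not in ("controls", "none"):
        raise ValueError(f"correction must be controls|none, got {opts.correction!r}")

    controls = control_mu_table(wells)
    exp = [w for w in wells if w.role == "experimental"]
    if not exp:
        raise ValueError("no experimental wells")

    if opts.correction == "controls":
        mu_assigned, prov = assign_control_mu(
            controls,
            [w.P0 for w in exp],
            strategy=opts.mu_strategy,
            n_bins=opts.n_bins,
        )
    else:
        mu_assigned = np.zeros(len(exp))
        prov = ["uncorrected"] * len(exp)

    m_prey_pg = carbon_from_volume(opts.prey_cell_volume, opts.prey_carbon)
    m_pred_ng = carbon_from_volume(opts.predator_cell_volume, opts.predator_carbon) / 1000.0

    rows = []
    for w, mu_c, pv in zip(exp, mu_assigned, prov):
        flags: list[str] = []
        r = specific_growth_rate(w.R0, w.Rt, w.t_days)
        mu_net = specific_growth_rate(w.P0, w.Pt, w.t_days)
        g = grazing_rate(mu_c, w.P0, w.Pt, w.t_days)
        p_mean = log_mean_density(w.P0, w.Pt)
        rm = _mean_predator(w.R0, w.Rt, opts.rm_method)
        p_for_i = p_mean if opts.ingestion_density == "mean" else w.P0
        i_cells, i_carbon = ingestion_rate(p_for_i, g, rm, m_pg=m_prey_pg)
        c, prop = clearance_and_proportion(i_cells, p_for_i)

        if g < 0:
            flags.append("negative_grazing")
        counts = [
            w.counted_prey_0, w.counted_prey_t, w.counted_pred_0, w.counted_pred_t,
        ]
        if any(cv is not None and cv < MIN_COUNTED_CELLS for cv in counts):
            flags.append("low_count")

        if i_carbon is not None and i_carbon > 0:
            gge = gross_growth_efficiency(r, m_pred_ng, i_carbon)
            gge_vol = gross_growth_efficiency_volume(
                r, opts.predator_cell_volume, i_cells, opts.prey_cell_volume
            )
            if not 0.0 < gge < 1.0:
                flags.append("gge_out_of_range")
        else:
            gge = gge_vol = float("nan")
            flags.append("gge_undefined")

        rows.append(
            {
                "well_id": w.well_id,
                "target_prey": w.target_prey,
                "P0": w.P0,
                "Pt": w.Pt,
                "P_mean": p_mean,
                "R0": w.R0,
                "Rt": w.Rt,
                "Rm": rm,
                "r": r,
                "mu_prey_net": mu_net,
                "mu_control": mu_c,
                "mu_provenance": pv,
                "g": g,
                "I_cells": i_cells,
                "I_carbon": i_carbon,
                "C": c,
                "proportion_ingested": prop,
                "GGE": gge,
                "GGE_volume": gge_vol,
                "flw_fraction": w.flw_fraction,
                "flags": ";".join(flags),
            }
        )

    rates = pd.DataFrame(rows)
    rates.attrs["correction"] = opts.correction
    rates.attrs["ingestion_density"] = opts.ingestion_density
    rates.attrs["mu_strategy"] = opts.mu_strategy if opts.correction == "controls" else None
    rates.attrs["rm_method"] = opts.rm_method
    return rates, controls
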