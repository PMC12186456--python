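"""Experiment-design calculator for dilution-series incubations.

Builds the bench sheet for a response experiment: a geometric
progression of target prey densities and, per container, the volumes of
dense prey culture (Dy2), predator culture (Dx) and diluent needed to
hit the targets in a fixed container volume.  Three diluent modes are
supported:

* ``FLW``   — filtered lake water (or filtered seawater) tops up each
  container; simplest, but the diluent fraction then varies with the
  prey level and can itself become a bias covariate.
* ``FPC``   — filtered prey culture as diluent, equalizing the dissolved
  background; since the predator volume Dx is constant across
  experimental containers, (Dy2 + FPC) is automatically pinned to
  V − Dx in every well.
* ``predator_filtrate`` — filtered predator culture as diluent, for
  species sensitive to any change of their conditioned medium.

Controls receive an identical but filtered predator-culture volume
(Dx_filt) in place of the live inoculum; optionally that share is
replaced by plain diluent (``controls_filtered_predator=False``),
emulating controls inoculated from predator-free cultures — the layout
that makes the diluent fraction systematically higher in controls.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .rates import MIN_COUNTED_CELLS, generation_time

__all__ = [
    "InfeasibleDesignError",
    "PLAN_COLUMNS",
    "target_density_series",
    "allocate_volumes",
    "design_checks",
    "culture_demand",
    "acclimatization_advice",
]

PLAN_COLUMNS = [
    "level",
    "role",
    "Pini",
    "Rini",
    "V",
    "Dy2",
    "Dx",
    "Dx_filt",
    "diluent_type",
    "diluent_mL",
    "warnings",
]

#: Recommended geometric-progression factor range between prey levels.
FACTOR_RANGE = (1.1, 1.5)
#: Tolerated relative spread of predator density across containers.
PREDATOR_SPREAD_TOL = 0.20


class InfeasibleDesignError(ValueError):
    """Target densities unreachable with the given stocks/volume."""


def target_density_series(p_min: float, p_max: float, factor: float) -> np.ndarray:
    """Geometric progression of target prey densities.

    P_k = p_min·factor^k for all k with P_k ≤ p_max.  Factors outside
    the recommended [1.1, 1.5] window trigger a UserWarning (too-coarse
    series under-resolve the curve; too-fine series waste containers).
    """
    if not (0 < p_min < p_max):
        raise ValueError(f"need 0 < p_min < p_max, got ({p_min}, {p_max})")
    if not 1.0 < factor <= 2.0:
        raise ValueError(f"factor must be in (1, 2], got {factor}")
    if not FACTOR_RANGE[0] <= factor <= FACTOR_RANGE[1]:
        warnings.warn(
            f"progression factor {factor} outside the recommended range "
            f"{FACTOR_RANGE}",
            UserWarning,
            stacklevel=2,
        )
    n = int(math.floor(math.log(p_max / p_min) / math.log(factor) + 1e-9)) + 1
    levels = p_min * factor ** np.arange(n)
    return levels[levels <= p_max * (1 + 1e-12)]


def allocate_volumes(
    targets,
    prey_stock_density: float,
    predator_stock_density: float,
    target_predator: float,
    container_volume: float,
    mode: str = "FLW",
    controls_every: int = 2,
    controls_filtered_predator: bool = True,
    rounding_mL: float = 0.01,
    carryover_prey_per_mL: float = 0.0,
) -> pd.DataFrame:
    """Per-container volume allocation for a target-density series.

    Parameters
    ----------
    targets : array-like
        Target prey densities Pini (cells mL⁻¹), ascending.
    prey_stock_density, predator_stock_density : float
        Densities of the stock cultures (cells mL⁻¹); must exceed the
        highest respective target.
    target_predator : float
        Target predator density Rini (cells mL⁻¹), identical in every
        experimental container.
    container_volume : float
        Working volume V of each container (mL).
    mode : {"FLW", "FPC", "predator_filtrate"}
        Diluent filling the remainder of each container.
    controls_every : int
        A predator-free control is placed at every ``controls_every``-th
        prey level (0 disables controls).
    controls_filtered_predator : bool
        When True, controls receive a filtered predator-culture volume
        equal to Dx; when False that share is folded into the diluent
        (controls inoculated from predator-free culture).
    rounding_mL : float
        Pipettable increment for Dy2/Dx; the diluent absorbs the
        rounding so each container still closes to V exactly.
    carryover_prey_per_mL : float
        Prey density in the predator stock (cells mL⁻¹) carried over
        with the inoculum; reported as an additive Pini correction in
        an extra ``carryover_prey`` column when non-zero.

    Returns
    -------
    DataFrame with :data:`PLAN_COLUMNS`, one row per container, in
    which Dy2 + Dx + Dx_filt + diluent_mL == V for every row.
    """
    targets = np.asarray(targets, dtype=float)
    if np.any(np.diff(targets) <= 0):
        raise ValueError("targets must be strictly ascending")
    if mode not in ("FLW", "FPC", "predator_filtrate"):
        raise ValueError(f"unknown dilution mode {mode!r}")
    V = container_volume
    if V <= 0:
        raise ValueError(f"container volume must be > 0, got {V}")
    if prey_stock_density < targets.max():
        raise InfeasibleDesignError(
            f"prey stock ({prey_stock_density} mL^-1) is below the highest "
            f"target ({targets.max()} mL^-1)"
        )
    if predator_stock_density < target_predator:
        raise InfeasibleDesignError(
            f"predator stock ({predator_stock_density} mL^-1) is below the "
            f"target ({target_predator} mL^-1)"
        )
    diluent_type = {"FLW": "FLW", "FPC": "FPC", "predator_filtrate": "Dx_filt"}[mode]

    def snap(x: float) -> float:
        return round(x / rounding_mL) * rounding_mL if rounding_mL > 0 else x

    dx = snap(V * target_predator / predator_stock_density)
    rows = []
    for i, pini in enumerate(targets):
        dy2 = snap(V * pini / prey_stock_density)
        remainder = V - dy2 - dx
        if remainder < -1e-9:
            raise InfeasibleDesignError(
                f"level {i} (Pini={pini:g}) needs {dy2 + dx:.2f} mL of culture "
                f"in a {V:g}-mL container"
            )
        rows.append(
            {
                "level": i,
                "role": "experimental",
                "Pini": pini,
                "Rini": target_predator,
                "V": V,
                "Dy2": dy2,
                "Dx": dx,
                "Dx_filt": 0.0,
                "diluent_type": diluent_type,
                "diluent_mL": max(remainder, 0.0),
                "warnings": "",
            }
        )
        if controls_every and i % controls_every == 0:
            dxf = dx if controls_filtered_predator else 0.0
            c_remainder = V - dy2 - dxf
            rows.append(
                {
                    "level": i,
                    "role": "control",
                    "Pini": pini,
                    "Rini": 0.0,
                    "V": V,
                    "Dy2": dy2,
                    "Dx": 0.0,
                    "Dx_filt": dxf,
                    "diluent_type": diluent_type,
                    "diluent_mL": max(c_remainder, 0.0),
                    "warnings": "",
                }
            )
    plan = pd.DataFrame(rows, columns=PLAN_COLUMNS)
    if carryover_prey_per_mL > 0:
        plan["carryover_prey"] = (
            plan["Dx"] * carryover_prey_per_mL / plan["V"]
        )
    return plan


def culture_demand(plan: pd.DataFrame) -> dict[str, float]:
    """Total stock-culture volumes (mL) the plan consumes.

    Filtered volumes (FPC diluent, Dx_filt) also have to be harvested
    from the respective stock culture before filtration, so they count
    towards the demand.
    """
    prey = float(plan["Dy2"].sum())
    if (plan["diluent_type"] == "FPC").any():
        prey += float(plan.loc[plan["diluent_type"] == "FPC", "diluent_mL"].sum())
    predator = float(plan["Dx"].sum() + plan["Dx_filt"].sum())
    if (plan["diluent_type"] == "Dx_filt").any():
        predator += float(
            plan.loc[plan["diluent_type"] == "Dx_filt", "diluent_mL"].sum()
        )
    return {"prey_culture_mL": prey, "predator_culture_mL": predator}


def design_checks(
    plan: pd.DataFrame,
    prey_subsample_mL: float = 1.0,
    predator_subsample_mL: float = 3.0,
) -> list[str]:
    """Advisory checks on a design plan (pure warnings, never errors).

    * predator density spread beyond ±20% across experimental containers
      (risk of predator interference confounding the prey-density axis);
    * expected counted cells below the 50-cell precision guideline given
      the counting-subsample volumes;
    * prey progression factors outside the recommended [1.1, 1.5];
    * missing predator-free controls.
    """
    notes: list[str] = []
    ex = plan[plan["role"] == "experimental"]
    r = ex["Rini"].to_numpy(dtype=float)
    if len(r) and r.min() > 0 and (r.max() - r.min()) / r.min() > PREDATOR_SPREAD_TOL:
        notes.append(
            f"predator targets spread {(r.max() - r.min()) / r.min():.0%} "
            f"(> {PREDATOR_SPREAD_TOL:.0%}) across containers"
        )
    for _, row in plan.iterrows():
        exp_pred = row["Rini"] * predator_subsample_mL
        if row["role"] == "experimental" and exp_pred < MIN_COUNTED_CELLS:
            notes.append(
                f"level {int(row['level'])}: expected predator count "
                f"{exp_pred:.0f} < {MIN_COUNTED_CELLS}"
            )
        exp_prey = row["Pini"] * prey_subsample_mL
        if exp_prey < MIN_COUNTED_CELLS:
            notes.append(
                f"level {int(row['level'])} ({row['role']}): expected prey count "
                f"{exp_prey:.0f} < {MIN_COUNTED_CELLS}"
            )
    pini = ex.sort_values("level")["Pini"].to_numpy(dtype=float)
    if len(pini) > 1:
        f = pini[1:] / pini[:-1]
        bad = (f < FACTOR_RANGE[0] - 1e-9) | (f > FACTOR_RANGE[1] + 1e-9)
        if bad.any():
            notes.append(
                f"{int(bad.sum())} neighboring prey levels outside the "
                f"recommended factor range {FACTOR_RANGE}"
            )
    if not (plan["role"] == "control").any():
        notes.append("no predator-free controls in the plan")
    return notes


def acclimatization_advice(rmax: float) -> str:
    """Generation-time bookkeeping for the acclimatization schedule."""
    g = generation_time(rmax)
    return (
        f"predator generation time G = ln2/rmax = {g:.2f} d; acclimatize for "
        f"at least one generation (~{g:.1f} d) per stepwise change and "
        f">= {g:.1f} d at the final target levels"
    )
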