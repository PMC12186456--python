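"""CSV interchange formats, pipeline configuration and the report bundle.

The wells CSV is the single interchange format between the simulator,
the bench and the analysis stages: one row per incubation container,
densities as non-negative numbers, predator columns left *empty* (not
zero) in control rows.  An empty cell means "not measured"; a zero means
"measured, none found" — the reader keeps the distinction.

``run_pipeline`` ties the stages together: per-well rates for every
requested correction variant, NR and FR fits for every requested
(transform × axis) combination, AICc rankings within comparable groups,
the type II/III verdict, a gross-growth-efficiency consistency block and
the covariate bias screen.  Every estimate carries its dataset-variant
provenance; refusals (e.g. log transform on data with negative
ingestion) are reported and the remaining variants continue.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biomass import (
    PREDATOR_CARBON,
    PREDATOR_CELL_VOLUME,
    PREY_CARBON,
    PREY_CELL_VOLUME,
    CarbonModel,
    carbon_from_volume,
)
from .fitting import (
    FitResult,
    TransformRefusalError,
    TypeVerdict,
    covariate_effects,
    discriminate_fr_type,
    fit_fr,
    fit_nr,
    rank_models,
)
from .rates import WellObservation, derive_rates, gross_growth_efficiency_volume

__all__ = [
    "WELLS_COLUMNS",
    "WellsFormatError",
    "read_wells",
    "write_wells",
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
]

WELLS_COLUMNS = [
    "well_id",
    "role",
    "target_prey",
    "P0",
    "Pt",
    "R0",
    "Rt",
    "counted_prey_0",
    "counted_prey_t",
    "counted_pred_0",
    "counted_pred_t",
    "subsample_mL",
    "t_days",
    "flw_fraction",
]

_PREDATOR_COLUMNS = ("R0", "Rt", "counted_pred_0", "counted_pred_t")


class WellsFormatError(ValueError):
    """Malformed wells CSV; messages carry 1-based data row numbers."""


def _parse_cell(raw: str, column: str, row: int) -> float | None:
    if raw is None or raw == "" or (isinstance(raw, float) and math.isnan(raw)):
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise WellsFormatError(
            f"row {row}, column {column!r}: cannot parse {raw!r} as a number"
        ) from None
    return value


def read_wells(path) -> list[WellObservation]:
    """Read and validate a wells CSV into observation records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in WELLS_COLUMNS if c not in df.columns]
    if missing:
        raise WellsFormatError(f"missing columns: {missing}")
    wells = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        role = rec["role"].strip()
        if role not in ("experimental", "control"):
            raise WellsFormatError(
                f"row {i}, column 'role': expected experimental|control, got {role!r}"
            )
        vals = {c: _parse_cell(rec[c], c, i) for c in WELLS_COLUMNS[2:]}
        if role == "control":
            filled = [c for c in _PREDATOR_COLUMNS if vals[c] is not None]
            if filled:
                raise WellsFormatError(
                    f"row {i}: control well has predator columns filled: {filled}"
                )
        for c in ("P0", "Pt", "t_days"):
            if vals[c] is None:
                raise WellsFormatError(f"row {i}, column {c!r}: value required")
            if vals[c] < 0:
                raise WellsFormatError(
                    f"row {i}, column {c!r}: negative density {vals[c]}"
                )
        try:
            wells.append(
                WellObservation(
                    well_id=rec["well_id"],
                    role=role,
                    **{k: v for k, v in vals.items() if k != "flw_fraction"},
                    flw_fraction=vals["flw_fraction"] or 0.0,
                )
            )
        except ValueError as exc:
            raise WellsFormatError(f"row {i}: {exc}") from exc
    return wells


def write_wells(wells: list[WellObservation], path) -> None:
    """Write observations to the wells CSV (empty cells for None)."""
    rows = []
    for w in wells:
        rows.append(
            {
                c: ("" if getattr(w, c) is None else getattr(w, c))
                for c in WELLS_COLUMNS
            }
        )
    pd.DataFrame(rows, columns=WELLS_COLUMNS).to_csv(path, index=False)


def write_provenance(path, *, seed=None, config=None) -> None:
    """Sidecar provenance file (seed, config, package version)."""
    payload: dict = {"package": "grazefit", "version": __version__}
    if seed is not None:
        payload["seed"] = int(seed)
    if config is not None:
        from .simulate import config_digest

        payload["config"] = dataclasses.asdict(config)
        payload["config_sha256"] = config_digest(config)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Which analysis variants :func:`run_pipeline` runs.

    The cross product corrections × transforms × axes is attempted for
    every FR model in ``fr_models``; inadmissible combinations (log
    transform on data with non-positive ingestion) are reported as
    refusals, not errors.
    """

    fr_models: tuple[str, ...] = ("FR2", "FR3", "FR3-theta=3", "FR-free-theta")
    fit_nr_model: bool = True
    corrections: tuple[str, ...] = ("controls", "none")
    transforms: tuple[str, ...] = ("none", "log")
    density_axes: tuple[str, ...] = ("initial", "mean")
    mu_strategy: str = "density_bins"
    n_bins: int = 3
    alpha: float = 0.05
    seed: int = 0
    prey_cell_volume: float = PREY_CELL_VOLUME
    predator_cell_volume: float = PREDATOR_CELL_VOLUME
    prey_carbon: CarbonModel = PREY_CARBON
    predator_carbon: CarbonModel = PREDATOR_CARBON

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            if f.name in ("prey_carbon", "predator_carbon"):
                v = CarbonModel(**v)
            elif isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, with full provenance."""

    rates: dict[str, pd.DataFrame]  # per correction variant
    controls: pd.DataFrame
    fits: list[FitResult]
    rankings: list[pd.DataFrame]
    verdict: TypeVerdict | None
    gge: pd.DataFrame
    covariates: pd.DataFrame
    messages: list[str] = field(default_factory=list)

    def fits_table(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            base = {
                "model_id": f.model_id,
                "transform": f.transform,
                "correction": f.correction,
                "density_axis": f.density_axis,
                "n": f.n,
                "rss": f.rss,
                "aicc": f.aicc,
            }
            for k, v in f.params.items():
                base[k] = v
                base[f"{k}_se"] = f.se.get(k)
                base[f"{k}_p"] = f.pvalues.get(k)
            for k, (v, se) in f.derived.items():
                base[k] = v
                base[f"{k}_se"] = se
            rows.append(base)
        return pd.DataFrame(rows)

    def report_text(self) -> str:
        lines = ["grazefit pipeline report", "=" * 26, ""]
        for f in self.fits:
            lines.append(f.summary())
            lines.append("")
        for rk in self.rankings:
            lines.append("ranking (" + rk.attrs.get("variant", "") + "):")
            lines.append(rk.to_string(index=False))
            lines.append("")
        if self.verdict is not None:
            v = self.verdict
            lines.append(
                f"type verdict: {v.verdict} (linear {v.linear_coef:.3g}, "
                f"p={v.linear_p:.3g}; quadratic {v.quadratic_coef:.3g}, "
                f"p={v.quadratic_p:.3g})"
            )
        if len(self.gge):
            lines.append("")
            lines.append("GGE consistency block:")
            lines.append(self.gge.to_string(index=False))
        if len(self.covariates):
            lines.append("")
            lines.append("covariate screen:")
            lines.append(self.covariates.to_string(index=False))
        if self.messages:
            lines.append("")
            lines.append("messages:")
            lines += [f"  - {m}" for m in self.messages]
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for variant, df in self.rates.items():
            df.to_csv(out / f"rates_{variant}.csv", index=False)
        self.controls.to_csv(out / "controls.csv", index=False)
        self.fits_table().to_csv(out / "fits.csv", index=False)
        if self.rankings:
            pd.concat(
                [rk.assign(variant=rk.attrs.get("variant", "")) for rk in self.rankings]
            ).to_csv(out / "rankings.csv", index=False)
        self.gge.to_csv(out / "gge.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        (out / "report.txt").write_text(self.report_text())


def run_pipeline(
    wells: list[WellObservation], config: PipelineConfig | None = None
) -> ReportBundle:
    """Run the full analysis over all requested dataset variants."""
    cfg = config or PipelineConfig()
    messages: list[str] = []
    rates_by_corr: dict[str, pd.DataFrame] = {}
    controls = None
    for corr in cfg.corrections:
        try:
            r, controls = derive_rates(
                wells,
                correction=corr,
                mu_strategy=cfg.mu_strategy,
                n_bins=cfg.n_bins,
                prey_cell_volume=cfg.prey_cell_volume,
                predator_cell_volume=cfg.predator_cell_volume,
                prey_carbon=cfg.prey_carbon,
                predator_carbon=cfg.predator_carbon,
            )
        except Exception as exc:
            messages.append(f"rates[{corr}]: {type(exc).__name__}: {exc}")
            continue
        rates_by_corr[corr] = r
        for _, row in r[r["flags"] != ""].iterrows():
            messages.append(
                f"rates[{corr}] well {row['well_id']}: flags {row['flags']}"
            )

    fits: list[FitResult] = []
    rankings: list[pd.DataFrame] = []
    nr_fit = None
    for corr, r in rates_by_corr.items():
        for axis in cfg.density_axes:
            if cfg.fit_nr_model:
                try:
                    f = fit_nr(r, density_axis=axis, seed=cfg.seed)
                    fits.append(f)
                    if nr_fit is None or f.aicc < nr_fit.aicc:
                        nr_fit = f
                except Exception as exc:
                    messages.append(f"NR[{corr},{axis}]: {type(exc).__name__}: {exc}")
            for transform in cfg.transforms:
                group = []
                for model in cfg.fr_models:
                    try:
                        group.append(
                            fit_fr(
                                r,
                                model=model,
                                transform=transform,
                                density_axis=axis,
                                seed=cfg.seed,
                            )
                        )
                    except TransformRefusalError as exc:
                        messages.append(f"{model}[{corr},{transform},{axis}]: {exc}")
                        break  # the whole transform group is inadmissible
                    except Exception as exc:
                        messages.append(
                            f"{model}[{corr},{transform},{axis}]: "
                            f"{type(exc).__name__}: {exc}"
                        )
                if group:
                    fits += group
                    rk = rank_models(group)
                    rk.attrs["variant"] = f"correction={corr},transform={transform},axis={axis}"
                    rankings.append(rk)

    # type discrimination: proportion ingested vs initial density, on the
    # uncorrected (all-positive where possible) dataset when available
    verdict = None
    vsource = rates_by_corr.get("none")
    if vsource is None:
        vsource = next(iter(rates_by_corr.values()), None)
    if vsource is not None:
        d = vsource.dropna(subset=["proportion_ingested", "P0"])
        try:
            verdict = discriminate_fr_type(
                d["P0"], d["proportion_ingested"], alpha=cfg.alpha
            )
        except ValueError as exc:
            messages.append(f"type discrimination skipped: {exc}")

    # GGE consistency: NR rmax against every fitted Imax
    gge_rows = []
    m_prey_pg = carbon_from_volume(cfg.prey_cell_volume, cfg.prey_carbon)
    m_pred_ng = carbon_from_volume(cfg.predator_cell_volume, cfg.predator_carbon) / 1e3
    if nr_fit is not None:
        rmax = nr_fit.params["rmax"]
        for f in fits:
            imax = f.derived.get("imax", (None, None))[0] or f.params.get("imax")
            if not imax or imax <= 0:
                continue
            gge_c = rmax * m_pred_ng / (imax * m_prey_pg / 1e3)
            gge_v = gross_growth_efficiency_volume(
                rmax, cfg.predator_cell_volume, imax, cfg.prey_cell_volume
            )
            gge_rows.append(
                {
                    "model_id": f.model_id,
                    "transform": f.transform,
                    "correction": f.correction,
                    "density_axis": f.density_axis,
                    "imax": imax,
                    "gge_carbon": gge_c,
                    "gge_volume": gge_v,
                    "plausible": bool(0 < gge_c < 1),
                }
            )
    gge = pd.DataFrame(
        gge_rows,
        columns=[
            "model_id", "transform", "correction", "density_axis",
            "imax", "gge_carbon", "gge_volume", "plausible",
        ],
    )
    for _, row in gge[~gge["plausible"]].iterrows():
        messages.append(
            f"GGE out of (0,1) for {row['model_id']} "
            f"[{row['correction']},{row['transform']},{row['density_axis']}]: "
            f"carbon basis {row['gge_carbon']:.3g}"
        )

    cov_source = rates_by_corr.get("controls")
    if cov_source is None:
        cov_source = next(iter(rates_by_corr.values()), None)
    covariates = (
        covariate_effects(cov_source, controls)
        if cov_source is not None
        else pd.DataFrame()
    )

    return ReportBundle(
        rates=rates_by_corr,
        controls=controls if controls is not None else pd.DataFrame(),
        fits=fits,
        rankings=rankings,
        verdict=verdict,
        gge=gge,
        covariates=covariates,
        messages=messages,
    )
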