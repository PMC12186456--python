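"""Nonlinear least-squares estimation and model selection.

Fits the threshold numerical response and the generalized Holling
functional-response family to per-well rate tables, ranks candidate
models by the small-sample Akaike criterion (AICc) and discriminates
type II from type III responses with the proportion-ingested polynomial
diagnostic.

Conventions
-----------
* Optimizer: trust-region least squares (``scipy.optimize.least_squares``)
  with multi-start initialization over log-spaced parameter grids; FR
  parameters are optimized in log space to enforce positivity.
* AICc parameter count k includes the residual variance (k = n_params+1),
  matching the convention of the standard AICc model-averaging tooling.
* Standard errors come from the linearized (Gauss-Newton) covariance
  s²·(JᵀJ)⁻¹; p-values are two-sided t tests with n − n_params df.
* Models fitted to different response vectors (different transform,
  control correction or density axis) are never ranked against each
  other: their likelihoods are incomparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .models import FRParams, NRParams, fr_predict, nr_predict

__all__ = [
    "FitResult",
    "TypeVerdict",
    "FitConvergenceError",
    "IncomparableFitsError",
    "TransformRefusalError",
    "FR_MODEL_IDS",
    "aicc",
    "fit_nr",
    "fit_fr",
    "rank_models",
    "discriminate_fr_type",
    "covariate_effects",
]

#: Candidate FR model identifiers understood by :func:`fit_fr`.
FR_MODEL_IDS = ("FR2", "FR3", "FR3-theta=<x>", "FR-free-theta", "FRmm")

#: Support threshold: models within this ΔAICc of the best have
#: substantial support and cannot be told apart on the criterion alone.
DELTA_AICC_SUPPORT = 2.0


class FitConvergenceError(RuntimeError):
    """All multi-start attempts failed to converge."""


class IncomparableFitsError(ValueError):
    """AICc comparison requested across different response vectors."""


class TransformRefusalError(ValueError):
    """Log transform requested on a response containing values <= 0."""


def aicc(rss: float, n: int, k: int) -> float:
    """Akaike information criterion with small-sample correction.

    AICc = n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1), with k the total number
    of estimated parameters *including* the residual variance.  The
    correction term vanishes as n grows, recovering AIC.
    """
    if rss <= 0:
        raise ValueError(f"rss must be > 0, got {rss}")
    if n - k - 1 <= 0:
        raise ValueError(f"AICc needs n > k + 1 (n={n}, k={k})")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _fit_aicc(rss: float, n: int, k: int) -> float:
    """AICc for a fit; a numerically perfect fit gets -inf rather than
    an error so that noiseless identifiability checks can still rank."""
    if rss <= 0 or rss < 1e-290:
        return -math.inf
    return aicc(rss, n, k)


@dataclass
class FitResult:
    """A fitted response model with its provenance.

    ``params``/``se``/``pvalues`` are keyed by parameter name; ``derived``
    carries delta-method quantities (e.g. Imax = 1/h).  Provenance fields
    record which dataset variant produced the estimates — these are
    required for any AICc comparison.
    """

    model_id: str
    params: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    rss: float
    n: int
    n_params: int
    aicc: float
    transform: str = "none"  # none | log
    correction: str | None = None  # controls | none
    density_axis: str = "initial"  # initial | mean
    derived: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    @property
    def provenance(self) -> tuple:
        return (self.transform, self.correction, self.density_axis, self.n)

    def predict(self, P):
        """Model prediction on the original (untransformed) response scale."""
        if self.model_id == "NR":
            return nr_predict(P, NRParams(**self.params))
        if self.model_id == "FRmm":
            from .models import fr_predict_mm

            return fr_predict_mm(P, self.params["imax"], self.params["k"])
        pars = FRParams(
            a=self.params["a"], h=self.params["h"], theta=self.params.get("theta", 1.0)
        )
        return fr_predict(P, pars)

    def summary(self) -> str:
        lines = [
            f"model {self.model_id}  (n={self.n}, RSS={self.rss:.6g}, "
            f"AICc={self.aicc:.2f})",
            f"  variant: transform={self.transform}, correction={self.correction}, "
            f"axis={self.density_axis}",
        ]
        for name in self.params:
            lines.append(
                f"  {name:8s} = {self.params[name]:.6g} "
                f"(SE {self.se[name]:.3g}, p {self.pvalues[name]:.3g})"
            )
        for name, (val, se) in self.derived.items():
            lines.append(f"  {name:8s} = {val:.6g} (SE {se:.3g}, derived)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# generic multistart NLS


def _nls(residual, starts, bounds, names, n, param_transform=None):
    """Multi-start trust-region least squares; returns the best solution.

    ``param_transform`` maps the optimization vector to natural-scale
    parameters and (via the chain rule for elementwise maps) their SEs.
    """
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residual,
                np.asarray(x0, dtype=float),
                bounds=bounds,
                method="trf",
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
                max_nfev=3000,
            )
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitConvergenceError(
            f"no multi-start converged for parameters {names} "
            f"(starts tried: {len(list(starts))})"
        )
    p = len(names)
    rss = float(2.0 * best.cost)
    dof = max(n - p, 1)
    s2 = rss / dof
    jtj = best.jac.T @ best.jac
    cov = s2 * np.linalg.pinv(jtj)
    se_opt = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    if param_transform is None:
        values, se = best.x, se_opt
    else:
        values, se = param_transform(best.x, se_opt)
    tstat = np.divide(
        values, se, out=np.full(p, np.inf), where=se > 0
    )
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=max(n - p, 1))
    return (
        {k: float(v) for k, v in zip(names, values)},
        {k: float(v) for k, v in zip(names, se)},
        {k: float(v) for k, v in zip(names, pvals)},
        rss,
        best,
    )


def _jittered(starts, rng, scale=0.1):
    out = list(starts)
    for x0 in starts:
        out.append(np.asarray(x0) * np.exp(rng.normal(0.0, scale, size=len(x0))))
    return out


def _axis_column(density_axis: str) -> str:
    if density_axis == "initial":
        return "P0"
    if density_axis == "mean":
        return "P_mean"
    raise ValueError(f"density_axis must be initial|mean, got {density_axis!r}")


# ---------------------------------------------------------------------------
# numerical response


def fit_nr(
    rates: pd.DataFrame,
    density_axis: str = "mean",
    seed: int = 0,
    n_starts: int = 8,
) -> FitResult:
    """Fit the threshold numerical response r(P) to a rate table.

    Needs columns ``r`` and the chosen density axis (``P0`` or
    ``P_mean``); at least 5 wells with finite growth rates.
    """
    col = _axis_column(density_axis)
    d = rates[[col, "r"]].dropna()
    P = d[col].to_numpy(dtype=float)
    r = d["r"].to_numpy(dtype=float)
    if len(P) < 5:
        raise ValueError(f"need >= 5 wells with finite r, got {len(P)}")

    rng = np.random.default_rng(seed)

    def residual(x):
        rmax, pprime, k2 = x
        xx = P - pprime
        return rmax * xx / (k2 + xx) - r

    rmax0 = max(r.max(), 1e-3)
    pgrid = [0.0, float(np.quantile(P, 0.05)), float(np.quantile(P, 0.2))]
    kgrid = [float(np.median(P)) * f for f in (0.3, 1.0, 3.0)]
    starts = [
        (rmax0 * f, pp, kk)
        for f in (1.0, 1.5)
        for pp in pgrid[:2]
        for kk in kgrid[::2]
    ]
    starts += [(rmax0, pgrid[2], kgrid[1])]
    starts = _jittered(starts[:n_starts], rng)
    bounds = ([1e-10, 0.0, 1e-6], [100.0, float(P.max()), 1e12])
    params, se, pvals, rss, best = _nls(
        residual, starts, bounds, ("rmax", "p_prime", "k2"), len(P)
    )
    return FitResult(
        model_id="NR",
        params=params,
        se=se,
        pvalues=pvals,
        rss=rss,
        n=len(P),
        n_params=3,
        aicc=_fit_aicc(rss, len(P), 3 + 1),
        transform="none",
        correction=rates.attrs.get("correction"),
        density_axis=density_axis,
        converged=bool(best.success),
        message=best.message,
    )


# ---------------------------------------------------------------------------
# functional response


def _parse_fr_model(model: str):
    """Return (theta_fixed_or_None, mm) for a model identifier string."""
    if model == "FR2":
        return 1.0, False
    if model == "FR3":
        return 2.0, False
    if model == "FRmm":
        return 1.0, True
    if model == "FR-free-theta":
        return None, False
    if model.startswith("FR3-theta="):
        return float(model.split("=", 1)[1]), False
    raise ValueError(f"unknown FR model id {model!r}; known: {FR_MODEL_IDS}")


def fit_fr(
    rates: pd.DataFrame,
    model: str = "FR2",
    transform: str = "none",
    density_axis: str = "initial",
    seed: int = 0,
    n_starts: int = 8,
) -> FitResult:
    """Fit a functional-response candidate model to a rate table.

    Parameters
    ----------
    rates : DataFrame
        Output of :func:`grazefit.rates.derive_rates`; needs ``I_cells``
        and the chosen density axis.  The control-correction provenance
        is read from ``rates.attrs``.
    model : str
        One of ``FR2`` (θ=1), ``FR3`` (θ=2), ``FR3-theta=<x>`` (fixed θ),
        ``FR-free-theta`` or ``FRmm`` (Michaelis–Menten form, θ=1).
    transform : {"none", "log"}
        ``log`` minimizes squared errors of ln(I) — only admissible when
        every ingestion value is positive (typically the uncorrected
        dataset); it tames the variance growing with prey density but
        can mask weak sigmoidality.
    """
    theta_fixed, mm = _parse_fr_model(model)
    col = _axis_column(density_axis)
    d = rates[[col, "I_cells"]].dropna()
    P = d[col].to_numpy(dtype=float)
    I = d["I_cells"].to_numpy(dtype=float)
    if len(P) < 6:
        raise ValueError(f"need >= 6 wells with finite I, got {len(P)}")
    if transform not in ("none", "log"):
        raise ValueError(f"transform must be none|log, got {transform!r}")
    if transform == "log" and np.any(I <= 0):
        raise TransformRefusalError(
            "log transform requires all ingestion rates > 0; the corrected "
            "dataset contains non-positive values — fit it untransformed or "
            "use the uncorrected (all-positive) variant"
        )

    rng = np.random.default_rng(seed)
    free_theta = theta_fixed is None
    imax_guess = max(I.max(), 1e-6)
    kq = [float(np.quantile(P, q)) for q in (0.4, 0.7)]

    if free_theta:
        names = ("a", "h", "theta")

        def natural(x):
            return np.exp(x[0]), np.exp(x[1]), x[2]

        def residual(x):
            a, h, th = natural(x)
            ap = a * P**th
            pred = ap / (1.0 + h * ap)
            return (np.log(pred) - np.log(I)) if transform == "log" else (pred - I)

        starts = []
        for th0 in (1.2, 2.0, 3.0):
            for f in (1.2, 2.5):
                h0 = 1.0 / (imax_guess * f)
                for k0 in kq:
                    starts.append((math.log(1.0 / (h0 * k0**th0)), math.log(h0), th0))
        bounds = ([-200.0, -40.0, 1.0], [200.0, 20.0, 6.0])

        def param_transform(x, se_opt):
            a, h, th = natural(x)
            return np.array([a, h, th]), np.array(
                [a * se_opt[0], h * se_opt[1], se_opt[2]]
            )

        n_params = 3
    else:
        th = theta_fixed
        names = ("a", "h")

        def residual(x):
            a, h = np.exp(x)
            ap = a * P**th
            pred = ap / (1.0 + h * ap)
            return (np.log(pred) - np.log(I)) if transform == "log" else (pred - I)

        starts = []
        for f in (1.2, 2.5, 5.0):
            h0 = 1.0 / (imax_guess * f)
            for k0 in kq:
                starts.append((math.log(1.0 / (h0 * k0**th)), math.log(h0)))
        bounds = ([-200.0, -40.0], [200.0, 20.0])

        def param_transform(x, se_opt):
            a, h = np.exp(x)
            return np.array([a, h]), np.array([a * se_opt[0], h * se_opt[1]])

        n_params = 2

    starts = _jittered(starts[:n_starts], rng)
    params, se, pvals, rss, best = _nls(
        residual, starts, bounds, names, len(P), param_transform=param_transform
    )

    derived = {}
    h = params["h"]
    if h > 0:
        derived["imax"] = (1.0 / h, se["h"] / h**2)  # delta method
        th_val = params.get("theta", theta_fixed)
        derived["k"] = ((1.0 / (params["a"] * h)) ** (1.0 / th_val), float("nan"))

    if mm:
        # report in the saturation parameterization (identical curve)
        a, hh = params["a"], params["h"]
        imax_v, imax_se = derived["imax"]
        k_v = 1.0 / (a * hh)
        params = {"imax": imax_v, "k": k_v}
        se = {"imax": imax_se, "k": float("nan")}
        pvals = {"imax": pvals["h"], "k": pvals["a"]}
        derived = {}

    theta_part = {} if (free_theta or mm) else {"theta": theta_fixed}
    result = FitResult(
        model_id=model,
        params={**params, **theta_part} if not mm else params,
        se={**se, **{k: 0.0 for k in theta_part}},
        pvalues={**pvals, **{k: float("nan") for k in theta_part}},
        rss=rss,
        n=len(P),
        n_params=n_params,
        aicc=_fit_aicc(rss, len(P), n_params + 1),
        transform=transform,
        correction=rates.attrs.get("correction"),
        density_axis=density_axis,
        derived=derived,
        converged=bool(best.success),
        message=best.message,
    )
    return result


# ---------------------------------------------------------------------------
# model ranking


def rank_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits by AICc with ΔAICc and support labels.

    All fits must share the same response vector (transform, correction,
    density axis and n); cross-variant rankings are refused because the
    underlying likelihoods are not comparable.  The ranking is invariant
    to input order (ties broken by model id).
    """
    if not fits:
        raise ValueError("no fits to rank")
    prov = {f.provenance for f in fits}
    if len(prov) > 1:
        raise IncomparableFitsError(
            f"fits come from different response vectors: {sorted(map(str, prov))}"
        )
    rows = sorted(fits, key=lambda f: (f.aicc, f.model_id))
    best = rows[0].aicc
    table = pd.DataFrame(
        {
            "model_id": [f.model_id for f in rows],
            "aicc": [f.aicc for f in rows],
            "delta_aicc": [f.aicc - best for f in rows],
            "rss": [f.rss for f in rows],
            "n_params": [f.n_params for f in rows],
        }
    )
    table["support"] = np.where(
        table["delta_aicc"] < DELTA_AICC_SUPPORT, "substantial", "weak"
    )
    return table


# ---------------------------------------------------------------------------
# FR type discrimination


@dataclass(frozen=True)
class TypeVerdict:
    """Outcome of the proportion-ingested polynomial diagnostic."""

    linear_coef: float
    linear_p: float
    quadratic_coef: float
    quadratic_p: float
    alpha: float
    verdict: str  # "typeII" | "typeIII" | "inconclusive"


def discriminate_fr_type(
    density,
    proportion,
    alpha: float = 0.05,
    weights=None,
) -> TypeVerdict:
    """Discriminate type II vs type III from proportion ingested vs density.

    Fits an OLS quadratic ``proportion ~ P + P²`` (WLS when ``weights``
    given).  A significantly positive linear together with a
    significantly negative quadratic term is the type III (unimodal
    clearance) signature; a significantly negative linear term with no
    negative quadratic is type II (monotone declining clearance);
    anything else is inconclusive.  Densities should span at least one
    order of magnitude for the quadratic to be identifiable.
    """
    P = np.asarray(density, dtype=float)
    y = np.asarray(proportion, dtype=float)
    if len(P) < 8:
        raise ValueError(f"need >= 8 (density, proportion) pairs, got {len(P)}")
    if P.min() <= 0 or P.max() / P.min() < 10:
        raise ValueError("densities must be positive and span >= one order of magnitude")
    scale = P.max()  # diagonal rescaling: t statistics are unaffected
    x = P / scale
    X = sm.add_constant(np.column_stack([x, x**2]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design matrix in type discrimination")
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    b1, b2 = res.params[1], res.params[2]
    p1, p2 = res.pvalues[1], res.pvalues[2]
    if b1 > 0 and p1 < alpha and b2 < 0 and p2 < alpha:
        verdict = "typeIII"
    elif b1 < 0 and p1 < alpha and not (b2 < 0 and p2 < alpha):
        verdict = "typeII"
    else:
        verdict = "inconclusive"
    return TypeVerdict(
        linear_coef=float(b1),
        linear_p=float(p1),
        quadratic_coef=float(b2),
        quadratic_p=float(p2),
        alpha=alpha,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# covariate diagnostics


def _ols_rows(y, X, names, response, subset):
    Xc = sm.add_constant(X)
    res = sm.OLS(y, Xc).fit()
    rows = []
    for i, name in enumerate(names, start=1):
        rows.append(
            {
                "response": response,
                "subset": subset,
                "term": name,
                "coef": float(res.params[i]),
                "se": float(res.bse[i]),
                "p": float(res.pvalues[i]),
                "n": int(res.nobs),
                "note": "",
            }
        )
    return rows


def covariate_effects(
    rates: pd.DataFrame, controls: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Bias-diagnostic screen for diluent (FLW) and predator-density effects.

    Three linear models, reported as a tidy slope/p table:

    * prey growth μ ~ FLW fraction, in controls (when supplied);
    * prey net growth μ ~ FLW fraction, in experimental wells;
    * ingestion I ~ FLW fraction + mean predator density Rm — a negative
      Rm slope indicates predator interference.

    A screen whose covariate is constant is skipped with a notice row.
    """
    rows: list[dict] = []

    def constant(v):
        v = np.asarray(v, dtype=float)
        return np.allclose(v, v[0])

    if controls is not None and len(controls) >= 3:
        if constant(controls["flw_fraction"]):
            rows.append(
                {
                    "response": "mu",
                    "subset": "controls",
                    "term": "flw_fraction",
                    "coef": float("nan"),
                    "se": float("nan"),
                    "p": float("nan"),
                    "n": len(controls),
                    "note": "constant_covariate",
                }
            )
        else:
            rows += _ols_rows(
                controls["mu"].to_numpy(float),
                controls[["flw_fraction"]].to_numpy(float),
                ["flw_fraction"],
                "mu",
                "controls",
            )

    d = rates.dropna(subset=["mu_prey_net", "flw_fraction"])
    if len(d) >= 3:
        if constant(d["flw_fraction"]):
            rows.append(
                {
                    "response": "mu",
                    "subset": "experimental",
                    "term": "flw_fraction",
                    "coef": float("nan"),
                    "se": float("nan"),
                    "p": float("nan"),
                    "n": len(d),
                    "note": "constant_covariate",
                }
            )
        else:
            rows += _ols_rows(
                d["mu_prey_net"].to_numpy(float),
                d[["flw_fraction"]].to_numpy(float),
                ["flw_fraction"],
                "mu",
                "experimental",
            )

    d2 = rates.dropna(subset=["I_cells", "flw_fraction", "Rm"])
    if len(d2) >= 4:
        X = d2[["flw_fraction", "Rm"]].to_numpy(float)
        keep = [i for i in range(2) if not constant(X[:, i])]
        names = [["flw_fraction", "Rm"][i] for i in keep]
        if names:
            rows += _ols_rows(
                d2["I_cells"].to_numpy(float), X[:, keep], names, "I", "experimental"
            )
        for i in (set(range(2)) - set(keep)):
            rows.append(
                {
                    "response": "I",
                    "subset": "experimental",
                    "term": ["flw_fraction", "Rm"][i],
                    "coef": float("nan"),
                    "se": float("nan"),
                    "p": float("nan"),
                    "n": len(d2),
                    "note": "constant_covariate",
                }
            )
    return pd.DataFrame(
        rows, columns=["response", "subset", "term", "coef", "se", "p", "n", "note"]
    )
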