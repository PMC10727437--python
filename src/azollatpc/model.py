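"""Asymmetric piecewise-Gaussian thermal performance curve (Room model).

The curve has four directly interpretable parameters:

    P(T) = p_max * exp(-a (T - t_opt)^2)   for T <= t_opt
    P(T) = p_max * exp(-b (T - t_opt)^2)   for T >  t_opt

with peak growth rate ``p_max`` (d⁻¹), optimal temperature ``t_opt`` (°C)
and shape coefficients ``a`` (rise side) and ``b`` (fall side), both > 0 and
in °C⁻².  The curve is continuous at ``t_opt``, strictly positive, and
defined at every temperature.

Fitting is by maximum likelihood with Gaussian residual error and a
study-level random effect on log peak height: study *j* observes a curve
with peak ``p_max * exp(u_j)``, ``u_j ~ N(0, sigma_study²)``, capturing
between-study differences in strains, culture conditions and experimenter
practice.  The random effect is marginalized per study by Gauss–Hermite
quadrature of the conditional likelihood, and the resulting integrated
likelihood is maximized over the six-dimensional parameter vector
(log p_max, t_opt, log a, log b, log sigma_resid, log sigma_study) with a
deterministic multi-start L-BFGS-B scheme.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from .records import RecordTable

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class RoomParams:
    """The four curve parameters: peak height, optimum, rise and fall shape."""

    p_max: float  # peak growth rate, d^-1
    t_opt: float  # optimal temperature, degC
    a: float      # rise-side shape coefficient, degC^-2 (T < t_opt)
    b: float      # fall-side shape coefficient, degC^-2 (T > t_opt)

    def __post_init__(self) -> None:
        if not (self.p_max > 0):
            raise ValueError(f"p_max must be > 0, got {self.p_max}")
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"a and b must be > 0, got a={self.a}, b={self.b}")
        if not math.isfinite(self.t_opt):
            raise ValueError(f"t_opt must be finite, got {self.t_opt}")


@dataclass(frozen=True)
class VarianceComponents:
    """Residual SD of the observations and SD of the study effect (log scale)."""

    sigma_resid: float
    sigma_study: float

    def __post_init__(self) -> None:
        if not (self.sigma_resid > 0):
            raise ValueError(f"sigma_resid must be > 0, got {self.sigma_resid}")
        if self.sigma_study < 0:
            raise ValueError(f"sigma_study must be >= 0, got {self.sigma_study}")


@dataclass
class FitConfig:
    """Optimizer settings; defaults reproduce a fit bit-for-bit per seed."""

    n_quadrature_nodes: int = 21
    n_starts: int = 8
    seed: int = 0
    tol: float = 1e-10
    # box bounds on the natural scale, motivated by the 5-50 degC
    # experimental span and observed RGR magnitudes
    bounds: dict = field(
        default_factory=lambda: {
            "p_max": (1e-4, 2.0),
            "t_opt": (0.0, 50.0),
            "a": (1e-6, 1.0),
            "b": (1e-6, 1.0),
            "sigma_resid": (1e-5, 5.0),
            "sigma_study": (1e-5, 5.0),
        }
    )

    def __post_init__(self) -> None:
        if self.n_quadrature_nodes < 3 or self.n_quadrature_nodes % 2 == 0:
            raise ValueError("n_quadrature_nodes must be an odd integer >= 3")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Fitted parameters, variance components and optimizer diagnostics."""

    params: RoomParams
    variance: VarianceComponents
    loglik: float
    converged: bool
    n_obs: int
    n_studies: int
    species: str | None = None
    per_start: list[dict] = field(default_factory=list)
    config: FitConfig | None = None

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "params": asdict(self.params),
            "variance": asdict(self.variance),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_studies": self.n_studies,
            # reserved for a future profile-likelihood implementation
            "confidence_intervals": None,
            "per_start": self.per_start,
            "config": {
                "n_quadrature_nodes": self.config.n_quadrature_nodes,
                "n_starts": self.config.n_starts,
                "seed": self.config.seed,
            }
            if self.config
            else None,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            params=RoomParams(**d["params"]),
            variance=VarianceComponents(**d["variance"]),
            loglik=d["loglik"],
            converged=d["converged"],
            n_obs=d["n_obs"],
            n_studies=d["n_studies"],
            species=d.get("species"),
            per_start=d.get("per_start", []),
        )


class ConvergenceError(RuntimeError):
    """All optimization starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, per_start: list[dict]):
        super().__init__(message)
        self.per_start = per_start


def room_performance(temperature, params: RoomParams):
    """Evaluate the curve at one or many temperatures (°C) -> RGR (d⁻¹).

    Vectorized over ``temperature``; scalar in, scalar out.
    """
    t = np.asarray(temperature, dtype=float)
    d2 = (t - params.t_opt) ** 2
    coef = np.where(t <= params.t_opt, params.a, params.b)
    out = params.p_max * np.exp(-coef * d2)
    return float(out) if np.isscalar(temperature) else out


def _grouped(table: RecordTable):
    """(study_ids, list of (T array, y array) per study) in first-seen order."""
    groups: dict[str, list[tuple[float, float]]] = {}
    for r in table:
        groups.setdefault(r.study_id, []).append((r.temperature, r.rgr))
    ids = list(groups)
    arrays = [
        (np.array([t for t, _ in g]), np.array([y for _, y in g]))
        for g in groups.values()
    ]
    return ids, arrays


def _data_nll_given_offset(temps, ys, params, sigma_resid, u):
    """Conditional -log f(y | u) for one study at offset(s) u.

    ``u`` may be a scalar or an array of quadrature nodes; returns matching
    shape (sum over the study's records).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    shape = room_performance(temps, params)  # (n_i,)
    mu = shape[None, :] * np.exp(u)[:, None]  # (k, n_i)
    resid = ys[None, :] - mu
    nll = 0.5 * np.sum(
        resid**2 / sigma_resid**2 + _LOG_2PI + 2.0 * math.log(sigma_resid), axis=1
    )
    return nll


def negative_log_likelihood(
    table: RecordTable,
    params: RoomParams,
    variance: VarianceComponents,
    study_effects: dict[str, float],
) -> float:
    """Joint negative log likelihood at *given* study offsets.

    Sum over records of the Gaussian negative log density of the observed RGR
    around the study-adjusted curve, plus the Gaussian negative log density
    of each offset under N(0, sigma_study²).  Requires sigma_study > 0 (the
    offset prior is degenerate otherwise; see :func:`integrated_nll` for the
    sigma_study = 0 limit).
    """
    if variance.sigma_resid <= 0:
        raise ValueError("sigma_resid must be > 0")
    if variance.sigma_study <= 0:
        raise ValueError("sigma_study must be > 0 for the joint likelihood")
    ids, arrays = _grouped(table)
    missing = [s for s in ids if s not in study_effects]
    if missing:
        raise ValueError(f"missing study offsets for: {missing}")
    total = 0.0
    for sid, (temps, ys) in zip(ids, arrays):
        u = study_effects[sid]
        total += float(
            _data_nll_given_offset(temps, ys, params, variance.sigma_resid, u)[0]
        )
        total += 0.5 * (
            u**2 / variance.sigma_study**2
            + _LOG_2PI
            + 2.0 * math.log(variance.sigma_study)
        )
    return total


def integrated_nll(
    table: RecordTable,
    params: RoomParams,
    variance: VarianceComponents,
    n_nodes: int = 21,
) -> float:
    """Negative log of the marginal likelihood, study effects integrated out.

    Per study the random offset u ~ N(0, sigma_study²) is integrated against
    the conditional likelihood by *adaptive* Gauss–Hermite quadrature: the
    nodes are recentred at the mode of the integrand and rescaled by its
    curvature, so the rule stays accurate even when the conditional
    likelihood is much narrower than the random-effect prior.  Everything is
    accumulated in log space, so the result is finite for any valid
    parameters.  With sigma_study = 0 this degenerates exactly to the
    fixed-effects NLL with all offsets at zero.
    """
    if variance.sigma_resid <= 0:
        raise ValueError("sigma_resid must be > 0")
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    ids, arrays = _grouped(table)
    s = variance.sigma_study
    sr = variance.sigma_resid
    if s == 0.0:
        return float(
            sum(
                _data_nll_given_offset(t, y, params, sr, 0.0)[0]
                for t, y in arrays
            )
        )
    nodes, weights = hermegauss(n_nodes)  # weight exp(-x^2/2), sum w = sqrt(2 pi)
    log_w = np.log(weights)
    total = 0.0
    for temps, ys in arrays:
        m = room_performance(temps, params)  # study curve at unit multiplier

        def h(u):
            """Log integrand: conditional log-lik + log prior density of u."""
            u = np.atleast_1d(np.asarray(u, dtype=float))
            data = -_data_nll_given_offset(temps, ys, params, sr, u)
            prior = -0.5 * (u**2 / s**2 + _LOG_2PI + 2.0 * math.log(s))
            return data + prior

        # locate the mode: coarse grid then damped, clamped Newton refinement
        u_cap = 30.0  # exp() stays finite; far beyond any plausible offset
        grid = np.linspace(-5.0 * s, 5.0 * s, 41)
        u_star = float(np.clip(grid[np.argmax(h(grid))], -u_cap, u_cap))
        for _ in range(30):
            e = math.exp(u_star)
            resid = ys - e * m
            d1 = float(np.sum(resid * e * m) / sr**2) - u_star / s**2
            d2 = float(np.sum((ys * e * m - 2.0 * e**2 * m**2)) / sr**2) - 1.0 / s**2
            if d2 >= -1e-300:
                break
            step = float(np.clip(d1 / d2, -1.0, 1.0))
            u_star = float(np.clip(u_star - step, -u_cap, u_cap))
            if abs(step) < 1e-12:
                break
        e = math.exp(u_star)
        d2 = float(np.sum((ys * e * m - 2.0 * e**2 * m**2)) / sr**2) - 1.0 / s**2
        scale = math.sqrt(-1.0 / d2) if d2 < 0.0 else s
        u_nodes = u_star + scale * nodes
        # log ∫ e^{h(u)} du ≈ log Σ w_k e^{x_k²/2} e^{h(u* + scale x_k)} + log scale
        total -= float(
            logsumexp(log_w + 0.5 * nodes**2 + h(u_nodes)) + math.log(scale)
        )
    return total


def _pack(params: RoomParams, variance: VarianceComponents) -> np.ndarray:
    return np.array(
        [
            math.log(params.p_max),
            params.t_opt,
            math.log(params.a),
            math.log(params.b),
            math.log(variance.sigma_resid),
            math.log(variance.sigma_study),
        ]
    )


def _unpack(theta: np.ndarray) -> tuple[RoomParams, VarianceComponents]:
    params = RoomParams(
        p_max=math.exp(theta[0]), t_opt=theta[1], a=math.exp(theta[2]), b=math.exp(theta[3])
    )
    variance = VarianceComponents(
        sigma_resid=math.exp(theta[4]), sigma_study=math.exp(theta[5])
    )
    return params, variance


def _start_points(table: RecordTable, config: FitConfig) -> list[np.ndarray]:
    """Deterministic data-driven starts: peak location/height plus jitter."""
    temps = np.array([r.temperature for r in table])
    ys = np.array([r.rgr for r in table])
    i_max = int(np.argmax(ys))
    p0 = max(float(ys[i_max]), 1e-3)
    t0 = float(temps[i_max])
    rng = np.random.default_rng(config.seed)
    starts = []
    base = np.array(
        [math.log(p0), t0, math.log(5e-3), math.log(5e-3), math.log(0.05), math.log(0.1)]
    )
    starts.append(base)
    for _ in range(config.n_starts - 1):
        jitter = rng.normal(0.0, [0.3, 3.0, 1.0, 1.0, 0.5, 0.5])
        starts.append(base + jitter)
    return starts


def fit_tpc(table: RecordTable, config: FitConfig | None = None,
            species: str | None = None) -> FitResult:
    """Fit the curve to one species' records by maximum integrated likelihood.

    Requires a non-empty single-species table with at least two distinct
    temperatures.  Runs ``config.n_starts`` L-BFGS-B optimizations from
    deterministic jittered starts; the lowest converged NLL wins, ties broken
    by start index.  Reproducible for a fixed ``config.seed``.
    """
    config = config or FitConfig()
    if len(table) == 0:
        raise ValueError("cannot fit an empty table")
    species_present = table.species
    if len(species_present) > 1:
        raise ValueError(
            f"table mixes species {sorted(species_present)}; fit one at a time"
        )
    temps = {r.temperature for r in table}
    if len(temps) < 2:
        raise ValueError(
            f"need at least 2 distinct temperatures, got {len(temps)}"
        )

    bkeys = ("p_max", "t_opt", "a", "b", "sigma_resid", "sigma_study")
    bounds = []
    for i, k in enumerate(bkeys):
        lo, hi = config.bounds[k]
        if k == "t_opt":
            bounds.append((lo, hi))
        else:
            bounds.append((math.log(lo), math.log(hi)))

    def objective(theta: np.ndarray) -> float:
        params, variance = _unpack(theta)
        return integrated_nll(table, params, variance, config.n_quadrature_nodes)

    per_start: list[dict] = []
    best = None
    for idx, theta0 in enumerate(_start_points(table, config)):
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective, theta0, method="L-BFGS-B", bounds=bounds, tol=config.tol
        )
        per_start.append(
            {
                "start": idx,
                "nll": float(res.fun),
                "converged": bool(res.success),
                "message": str(res.message),
                "nit": int(res.nit),
            }
        )
        if res.success and (best is None or res.fun < best[0] - 0.0):
            best = (float(res.fun), idx, res.x.copy())
    if best is None:
        raise ConvergenceError("no optimization start converged", per_start)
    nll, _, theta = best
    params, variance = _unpack(theta)
    n_ids = len(table.study_ids)
    return FitResult(
        params=params,
        variance=variance,
        loglik=-nll,
        converged=True,
        n_obs=len(table),
        n_studies=n_ids,
        species=species or (next(iter(species_present)) if species_present else None),
        per_start=per_start,
        config=config,
    )


def plot_fit(table: RecordTable, result: FitResult, path: str | Path) -> None:
    """Diagnostic plot: fitted curve over the observed points (cosmetic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    temps = np.array([r.temperature for r in table])
    ys = np.array([r.rgr for r in table])
    grid = np.linspace(min(temps.min(), 0), max(temps.max(), 50), 400)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(temps, ys, s=12, alpha=0.6, label="observations")
    ax.plot(grid, room_performance(grid, result.params), "k-", label="fitted curve")
    ax.set_xlabel("Temperature (°C)")
    ax.set_ylabel("RGR (d$^{-1}$)")
    ax.set_title(result.species or "thermal performance curve")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
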