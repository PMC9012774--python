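"""Single-population demographic inference from the site frequency spectrum.

The expected SFS under a piecewise size history is computed by integrating
the closed moment system of the Wright–Fisher diffusion: for a sample of
``n`` allele copies the expected class counts F_i(t), i = 1..n−1, obey a
linear ODE

    dF/dt = D F / ν(t) + s,

where ``D`` is the tridiagonal drift operator

    (D F)_i = ½ [ (i−1)(n−i+1) F_{i−1} − 2 i(n−i) F_i + (i+1)(n−i−1) F_{i+1} ],

``s = (n/2)·e_1`` is the mutational influx into the singleton class per
unit θ, ν(t) the size ratio, and time runs in units of 2·Nref
generations. The neutral system is exactly closed, and its constant-size
equilibrium is the classical ξ_i = θ/i. Constant epochs are propagated
exactly through the (cached) eigendecomposition of ``D``; exponential
epochs are integrated with a stiff ODE solver at tight tolerance.

Fitting uses the Poisson random-field composite likelihood: each SFS
class is an independent Poisson count with mean θ·ξ_i(params), so θ is
profiled analytically (θ̂ = Σ obs / Σ ξ) and never enters the optimiser
or the parameter count k. Model selection is by AIC = 2k − 2·logL with
Akaike weights; uncertainty comes from a parametric goodness-of-fit
bootstrap and a non-parametric bootstrap over RAD loci.

Four size-history models are provided: ``two_epoch`` (instantaneous
change to ν at time T), ``growth`` (exponential change reaching ν at
present, started T ago), ``bottlegrowth`` (instantaneous change to νB at
T followed by exponential change to ν at present) and ``three_epoch``
(size νB for duration TB, then ν for the final TF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint
from scipy.linalg import eigh_tridiagonal
from scipy.special import gammaln

from .genotypes import GenotypeMatrix
from .sfs_ops import SiteFrequencySpectrum, fold_sfs, sfs_from_genotypes, thin_one_snp_per_locus
from .simgen import SizeHistory


# ======================================================================
# Models
# ======================================================================

@dataclass(frozen=True)
class DemographicModel:
    """A named single-population size-history parameterisation.

    ``k`` (the AIC parameter count) equals the number of shape/time
    parameters; the scaled mutation rate θ is profiled out analytically
    and not counted.
    """

    name: str
    param_names: tuple
    lower: tuple
    upper: tuple

    @property
    def k(self) -> int:
        return len(self.param_names)

    def history(self, params) -> SizeHistory:
        p = dict(zip(self.param_names, params))
        if self.name == "two_epoch":
            return SizeHistory.two_epoch(p["nu"], p["T"])
        if self.name == "growth":
            return SizeHistory.growth(p["nu"], p["T"])
        if self.name == "bottlegrowth":
            return SizeHistory.bottlegrowth(p["nuB"], p["nu"], p["T"])
        if self.name == "three_epoch":
            return SizeHistory.three_epoch(p["nuB"], p["nu"], p["TB"], p["TF"])
        raise ValueError(f"unknown model {self.name!r}")

    def validate(self, params) -> None:
        params = np.asarray(params, dtype=float)
        if params.shape != (self.k,):
            raise ValueError(f"{self.name} expects {self.k} parameters")
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        if np.any(params <= 0):
            raise ValueError("size ratios must be > 0 and times >= 0 (strictly positive here)")


_NU_BOUNDS = (1e-3, 1e3)
_T_BOUNDS = (1e-4, 5.0)

MODELS = {
    "two_epoch": DemographicModel(
        "two_epoch", ("nu", "T"), (_NU_BOUNDS[0], _T_BOUNDS[0]), (_NU_BOUNDS[1], _T_BOUNDS[1])
    ),
    "growth": DemographicModel(
        "growth", ("nu", "T"), (_NU_BOUNDS[0], _T_BOUNDS[0]), (_NU_BOUNDS[1], _T_BOUNDS[1])
    ),
    "bottlegrowth": DemographicModel(
        "bottlegrowth",
        ("nuB", "nu", "T"),
        (_NU_BOUNDS[0], _NU_BOUNDS[0], _T_BOUNDS[0]),
        (_NU_BOUNDS[1], _NU_BOUNDS[1], _T_BOUNDS[1]),
    ),
    "three_epoch": DemographicModel(
        "three_epoch",
        ("nuB", "nu", "TB", "TF"),
        (_NU_BOUNDS[0], _NU_BOUNDS[0], _T_BOUNDS[0], _T_BOUNDS[0]),
        (_NU_BOUNDS[1], _NU_BOUNDS[1], _T_BOUNDS[1], _T_BOUNDS[1]),
    ),
}


def get_model(model) -> DemographicModel:
    if isinstance(model, DemographicModel):
        return model
    return MODELS[model]


# ======================================================================
# Expected SFS solver
# ======================================================================

_OPERATOR_CACHE: dict = {}


def _drift_operator(n: int):
    """Dense D, its symmetrising diagonal, eigenvalues and eigenvectors.

    D is similar to a symmetric tridiagonal matrix via a positive
    diagonal scaling, so its eigendecomposition is computed stably with
    ``eigh_tridiagonal`` and cached per sample size.
    """
    if n in _OPERATOR_CACHE:
        return _OPERATOR_CACHE[n]
    i = np.arange(1, n)
    diag = -(i * (n - i)).astype(float)
    sub = 0.5 * (i[1:] - 1) * (n - i[1:] + 1)  # row i, col i-1: (i-1)(n-i+1)
    sup = 0.5 * (i[:-1] + 1) * (n - i[:-1] - 1)
    D = np.diag(diag) + np.diag(sub, -1) + np.diag(sup, 1)
    # symmetrise: off-diagonal of the similar symmetric matrix
    off = np.sqrt(sub * sup)
    lam, W = eigh_tridiagonal(diag, off)
    # diagonal similarity d: d[i+1]/d[i] = sqrt(sub[i+1->]/sup[i])
    d = np.ones(n - 1)
    for j in range(1, n - 1):
        d[j] = d[j - 1] * math.sqrt(sub[j - 1] / sup[j - 1])
    _OPERATOR_CACHE[n] = (D, d, lam, W)
    return _OPERATOR_CACHE[n]


def _propagate_constant(F, nu, duration, n):
    """Exact solution of dF/dt = D F/ν + s over a constant-size epoch."""
    _, d, lam, W = _drift_operator(n)
    i = np.arange(1, n)
    F_eq = nu / i
    y = (F - F_eq) / d
    coef = W.T @ y
    coef *= np.exp(lam * (duration / nu))
    return F_eq + d * (W @ coef)


def _propagate_exponential(F, nu_start, nu_end, duration, n):
    """Integrate one epoch with exponentially varying size.

    ``nu_start`` is the recent-boundary ratio, ``nu_end`` the ancient one;
    integration runs forward in real time from the ancient boundary.
    """
    D, _, _, _ = _drift_operator(n)
    s = np.zeros(n - 1)
    s[0] = n / 2.0
    lam_rate = math.log(nu_start / nu_end) / duration  # growth forward in time

    def nu_of(u):
        return nu_end * math.exp(lam_rate * u)

    def rhs(y, u):
        return D @ y / nu_of(u) + s

    def jac(y, u):
        return D / nu_of(u)

    sol = odeint(
        rhs,
        F,
        [0.0, duration],
        Dfun=jac,
        rtol=1e-10,
        atol=1e-12,
        mxstep=50000,
    )
    out = sol[-1]
    if not np.all(np.isfinite(out)):
        raise RuntimeError(
            f"expected-SFS integration failed on exponential epoch "
            f"(nu {nu_end}->{nu_start}, duration {duration})"
        )
    return out


def expected_sfs(model, params, n: int) -> SiteFrequencySpectrum:
    """Expected unfolded SFS per unit θ for ``n`` allele copies.

    Starts at the ancestral constant-size equilibrium ξ_i = 1/i and
    integrates the moment system through the model's epochs up to the
    present. Deterministic; entries are an expected density, not counts.
    """
    model = get_model(model)
    model.validate(params)
    if n < 4:
        raise ValueError("need n >= 4 allele copies")
    history = model.history(np.asarray(params, dtype=float))
    return expected_sfs_from_history(history, n)


def expected_sfs_from_history(history: SizeHistory, n: int) -> SiteFrequencySpectrum:
    i = np.arange(1, n)
    ancient = history.epochs[-1]
    F = ancient.nu_start / i  # equilibrium of the most ancient (constant) epoch
    for ep in reversed(history.epochs[:-1]):  # past -> present
        if ep.duration < 1e-12:  # no time for drift to act
            continue
        if ep.is_constant:
            F = _propagate_constant(F, ep.nu_start, ep.duration, n)
        else:
            F = _propagate_exponential(F, ep.nu_start, ep.nu_end, ep.duration, n)
    F = np.maximum(F, 0.0)
    return SiteFrequencySpectrum(n=n, values=F, folded=False, kind="density")


# ======================================================================
# Poisson random-field composite likelihood
# ======================================================================

def loglik(obs: SiteFrequencySpectrum, model_sfs: SiteFrequencySpectrum):
    """Composite log-likelihood and the analytic θ̂.

    Each class is Poisson with mean θ·ξ_i; the profile maximiser is
    θ̂ = Σ obs_i / Σ ξ_i, and the returned log-likelihood is evaluated at
    θ̂: Σ_i [obs_i·ln(θ̂ ξ_i) − θ̂ ξ_i − ln(obs_i!)].
    """
    if obs.n != model_sfs.n or obs.folded != model_sfs.folded:
        raise ValueError("observed and model SFS must share n and fold state")
    o = np.asarray(obs.values, dtype=float)
    xi = np.asarray(model_sfs.values, dtype=float)
    if o.size == 0:
        raise ValueError("empty observed SFS")
    if np.any((xi <= 0) & (o > 0)):
        return -np.inf, 0.0
    xi_sum = xi.sum()
    if xi_sum <= 0:
        raise ValueError("model SFS has no mass")
    theta_hat = float(o.sum() / xi_sum)
    mean = theta_hat * xi
    mask = mean > 0
    ll = float(
        np.sum(o[mask] * np.log(mean[mask]) - mean[mask] - gammaln(o[mask] + 1.0))
        - np.sum(mean[~mask])
    )
    return ll, theta_hat


# ======================================================================
# Multi-round optimisation
# ======================================================================

@dataclass
class FitResult:
    """Best fit of one demographic model to an observed SFS."""

    model: DemographicModel
    params: np.ndarray
    theta_hat: float
    loglik: float
    aic: float
    n: int
    folded: bool
    trace: list = field(default_factory=list)

    @property
    def params_dict(self) -> dict:
        return dict(zip(self.model.param_names, map(float, self.params)))


def _objective_factory(model, obs):
    n = obs.n

    def negloglik(log_params):
        params = np.exp(log_params)
        try:
            xi = expected_sfs(model, params, n)
        except (RuntimeError, ValueError):
            return 1e12
        if obs.folded:
            xi = fold_sfs(xi)
        ll, _ = loglik(obs, xi)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    return negloglik


def optimize(
    model,
    obs: SiteFrequencySpectrum,
    rounds: int = 4,
    reps_per_round: int = 50,
    maxiter: int = 25,
    seed: int = 0,
    init_params=None,
) -> FitResult:
    """Multi-round randomised local optimisation of a size-history model.

    Round 1 starts each replicate from an independent log-uniform draw
    inside the box bounds (or from a perturbation of ``init_params`` when
    given); every later round perturbs the incumbent best replicate by a
    multiplicative log-uniform fold that shrinks as 2^(1/round). Each
    replicate runs bounded L-BFGS-B in log-parameter space capped at
    ``maxiter`` iterations. The overall best replicate is returned;
    deterministic under ``seed``.
    """
    from scipy.optimize import minimize

    model = get_model(model)
    if obs.total() <= 0:
        raise ValueError("observed SFS has no polymorphic sites")
    rng = np.random.default_rng(seed)
    lo = np.log(np.asarray(model.lower, dtype=float))
    hi = np.log(np.asarray(model.upper, dtype=float))
    bounds = list(zip(lo, hi))
    fun = _objective_factory(model, obs)

    best_x, best_f = None, np.inf
    trace = []
    failures = []
    for rnd in range(1, rounds + 1):
        fold = math.log(2.0 ** (1.0 / rnd))
        for rep in range(reps_per_round):
            if best_x is None:
                if init_params is not None:
                    x0 = np.log(np.asarray(init_params, dtype=float))
                    x0 = x0 + rng.uniform(-math.log(2.0), math.log(2.0), size=len(lo))
                else:
                    x0 = rng.uniform(lo, hi)
            else:
                x0 = best_x + rng.uniform(-fold, fold, size=len(lo))
            x0 = np.clip(x0, lo, hi)
            try:
                res = minimize(
                    fun,
                    x0,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter},
                )
            except Exception as exc:  # noqa: BLE001 - collected as diagnostics
                failures.append(f"round {rnd} rep {rep}: {exc}")
                continue
            if res.fun < best_f:
                best_f = res.fun
                best_x = res.x
        trace.append(
            {
                "round": rnd,
                "loglik": -best_f if best_x is not None else None,
                "params": None if best_x is None else np.exp(best_x),
            }
        )
    if best_x is None:
        raise RuntimeError("all optimisation replicates failed: " + "; ".join(failures))
    params = np.exp(best_x)
    xi = expected_sfs(model, params, obs.n)
    if obs.folded:
        xi = fold_sfs(xi)
    ll, theta_hat = loglik(obs, xi)
    aic = 2 * model.k - 2 * ll
    return FitResult(model, params, theta_hat, ll, aic, obs.n, obs.folded, trace)


# ======================================================================
# Model selection
# ======================================================================

def model_selection(fits) -> pd.DataFrame:
    """AIC model-selection table (ascending AIC).

    Columns: model, k, loglik, AIC, dAIC, rel_lik (exp(−ΔAIC/2)), wAIC
    (normalised relative likelihoods) and cum_wAIC. Values are exact;
    use :func:`format_selection_table` for 2-decimal presentation.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    names = [f.model.name for f in fits]
    if len(set(names)) != len(names):
        raise ValueError("duplicated model names in selection table")
    df = pd.DataFrame(
        {
            "model": names,
            "k": [f.model.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "AIC": [f.aic for f in fits],
        }
    ).sort_values("AIC", kind="mergesort", ignore_index=True)
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    df["rel_lik"] = np.exp(-df["dAIC"] / 2.0)
    df["wAIC"] = df["rel_lik"] / df["rel_lik"].sum()
    df["cum_wAIC"] = df["wAIC"].cumsum()
    return df


def selection_table_from_loglik(names, ks, logliks) -> pd.DataFrame:
    """Model-selection arithmetic from externally supplied log-likelihoods."""
    fits = []
    for name, k, ll in zip(names, ks, logliks):
        model = DemographicModel(name, tuple(f"p{i}" for i in range(k)), (0,) * k, (1,) * k)
        fits.append(
            FitResult(model, np.ones(k), 0.0, ll, 2 * k - 2 * ll, 0, False)
        )
    return model_selection(fits)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, as tables are conventionally printed."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_selection_table(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = df.copy()
    for col in ("loglik", "AIC", "dAIC", "rel_lik", "wAIC", "cum_wAIC"):
        out[col] = [round_half_up(v, decimals) for v in out[col]]
    return out


# ======================================================================
# Bootstraps
# ======================================================================

@dataclass
class GofReport:
    """Parametric-bootstrap goodness-of-fit summary."""

    empirical_loglik: float
    sim_logliks: np.ndarray
    quantile: float
    within_range: bool


def gof_parametric_bootstrap(
    fit: FitResult,
    obs: SiteFrequencySpectrum,
    n_reps: int = 100,
    seed: int = 0,
    rounds: int = 2,
    reps_per_round: int = 10,
    maxiter: int = 25,
) -> GofReport:
    """Simulate Poisson SFS draws from the fitted model and refit each.

    The empirical composite log-likelihood is compared with the
    distribution of refit log-likelihoods; a well-fitting model leaves
    the empirical value inside the simulated range.
    """
    rng = np.random.default_rng(seed)
    xi = expected_sfs(fit.model, fit.params, obs.n)
    if obs.folded:
        xi = fold_sfs(xi)
    mean = fit.theta_hat * xi.values
    sims = np.empty(n_reps)
    for rep in range(n_reps):
        draw = rng.poisson(mean).astype(float)
        sim_obs = SiteFrequencySpectrum(obs.n, draw, folded=obs.folded, kind="counts")
        refit = optimize(
            fit.model,
            sim_obs,
            rounds=rounds,
            reps_per_round=reps_per_round,
            maxiter=maxiter,
            seed=int(rng.integers(2**31)),
            init_params=fit.params,
        )
        sims[rep] = refit.loglik
    quantile = float(np.mean(sims <= fit.loglik))
    within = bool(sims.min() <= fit.loglik <= sims.max())
    return GofReport(fit.loglik, sims, quantile, within)


@dataclass
class BootstrapCIs:
    """Percentile bootstrap confidence intervals per model parameter."""

    model: DemographicModel
    point: np.ndarray
    theta_point: float
    replicates: np.ndarray  # (n_reps, k) parameter draws
    theta_replicates: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.model.param_names),
                "point": self.point,
                "ci_low": self.lower,
                "ci_high": self.upper,
            }
        )


def resample_loci(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Resample RAD loci with replacement (the bootstrap unit)."""
    rng = np.random.default_rng(seed)
    loci = sorted(set(G.site_loci.tolist()))
    if len(loci) < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    picks = rng.integers(len(loci), size=len(loci))
    sites_of = {}
    for s, locus in enumerate(G.site_loci):
        sites_of.setdefault(locus, []).append(s)
    cols, new_loci, new_pos = [], [], []
    for copy_i, pick in enumerate(picks):
        locus = loci[pick]
        for s in sites_of[locus]:
            cols.append(s)
            new_loci.append(f"{locus}#b{copy_i}")
            new_pos.append(int(G.site_pos[s]))
    out = G.subset_sites(np.array(cols, dtype=int))
    out.site_loci = np.array(new_loci, dtype=object)
    out.site_pos = np.array(new_pos, dtype=int)
    out.n_loci_assayed = G.n_loci_assayed
    return out


def ci_nonparametric_bootstrap(
    G: GenotypeMatrix,
    model,
    point_fit: FitResult,
    n_reps: int = 100,
    seed: int = 0,
    project_to: int | None = None,
    fold: bool = True,
    rounds: int = 2,
    reps_per_round: int = 10,
    maxiter: int = 25,
) -> BootstrapCIs:
    """95% percentile CIs by resampling loci with replacement.

    Each bootstrap replicate resamples loci, rebuilds the SFS through the
    same thin → project → fold pipeline, and refits the model starting
    from the point estimate.
    """
    model = get_model(model)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_reps, model.k))
    thetas = np.empty(n_reps)
    for rep in range(n_reps):
        Gb = resample_loci(G, seed=int(rng.integers(2**31)))
        Gb = thin_one_snp_per_locus(Gb, seed=int(rng.integers(2**31)))
        sfs = sfs_from_genotypes(Gb, fold=fold, project_to=project_to)
        refit = optimize(
            model,
            sfs,
            rounds=rounds,
            reps_per_round=reps_per_round,
            maxiter=maxiter,
            seed=int(rng.integers(2**31)),
            init_params=point_fit.params,
        )
        reps[rep] = refit.params
        thetas[rep] = refit.theta_hat
    lower = np.percentile(reps, 2.5, axis=0)
    upper = np.percentile(reps, 97.5, axis=0)
    return BootstrapCIs(model, point_fit.params, point_fit.theta_hat, reps, thetas, lower, upper)


# ======================================================================
# Demographic units
# ======================================================================

@dataclass
class DemographicUnits:
    """Model parameters converted to individuals and years.

    Nref = θ̂ / (4·μ·L) diploid individuals; a scaled time T becomes
    T × 2·Nref × g years for generation time g.
    """

    model_name: str
    Nref: float
    size_ratios: dict
    times_years: dict
    mu: float
    L: float
    gen_time: float


def to_demographic_units(
    fit: FitResult, mu: float, L: float, gen_time: float
) -> DemographicUnits:
    if mu <= 0 or L <= 0 or gen_time <= 0:
        raise ValueError("mu, L and generation time must be positive")
    if fit.theta_hat <= 0:
        raise ValueError("theta_hat is zero; cannot convert to units")
    nref = fit.theta_hat / (4.0 * mu * L)
    ratios, times = {}, {}
    for name, val in fit.params_dict.items():
        if name.startswith("T"):
            times[name] = val * 2.0 * nref * gen_time
        else:
            ratios[name] = val
    return DemographicUnits(fit.model.name, nref, ratios, times, mu, L, gen_time)


def times_to_years(model: DemographicModel, params, theta, mu, L, gen_time) -> dict:
    """Convert one parameter vector's time entries to years (CI helper)."""
    nref = theta / (4.0 * mu * L)
    out = {}
    for name, val in zip(model.param_names, params):
        if name.startswith("T"):
            out[name] = float(val) * 2.0 * nref * gen_time
    return out
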