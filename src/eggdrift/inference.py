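"""Negative-binomial maximum-likelihood fitting of the dispersal model.

The per-minute egg counts from the towed imaging system are fitted to the
separable diffusion-mortality field.  The expected concentration (eggs
per litre) at observation i is

    E[Y_i] = exp(beta) * C(x_i, y_i, z_i, t_i) / 1000,

with C the 3-D model field in relative units per m^3 and beta a free
log-scale factor absorbing the released egg number.  The likelihood is
evaluated on the integer image counts with the sampled volume (litres per
minute) as exposure, so the expected count is E[Y_i] * volume_i; counts
are overdispersed with a negative-binomial law of size k (variance
m + m^2/k, Poisson as k -> infinity).

Estimation follows the usual ML workflow: quasi-Newton optimization on
log-transformed positive parameters with jittered multi-starts, 95%
confidence intervals from likelihood profiles (re-optimizing the other
parameters at each profile point), AIC over the lattice of nested
submodels, and deviance explained relative to an intercept-only
negative-binomial null.

Usage follows the Model/Results idiom::

    model = EggDispersalModel(obs, vertical, ModelSpec.full())
    res = model.fit(seed=0)
    res.summary()
    res.profile_interval("mu")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .tracks import validate_observations
from .vertical import VerticalConcentration

__all__ = [
    "ModelSpec",
    "EggDispersalModel",
    "EggDispersalResults",
    "nb_neg_loglik",
    "fit_ml",
    "profile_interval",
    "model_selection_table",
    "deviance_explained",
    "profile_interval_1d",
]

_PENALTY = 1e10
#: chi^2_1(0.95)/2, the log-likelihood drop defining a 95% profile interval
PROFILE_RISE_95 = float(stats.chi2.ppf(0.95, df=1) / 2.0)

# box bounds for the packed (log-scale) parameters
_BOUNDS = {
    "beta": (-60.0, 60.0),
    "log_Kx": (np.log(1e-1), np.log(1e8)),
    "log_Ky": (np.log(1e-1), np.log(1e8)),
    "log_mu": (np.log(1e-5), np.log(1e2)),
    "log_k": (np.log(1e-4), np.log(1e7)),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which dispersal parameters are free; beta and k are always free.

    ``free_ky=False`` with ``free_kx=True`` means isotropic diffusion
    (Ky = Kx); ``free_mu=False`` fixes mortality at zero; all flags off is
    the intercept-only null (constant expected concentration).
    """

    free_kx: bool = True
    free_ky: bool = True
    free_mu: bool = True
    name: str = "full"

    def __post_init__(self) -> None:
        if self.free_ky and not self.free_kx:
            raise ValueError("free_ky requires free_kx (use free_kx for isotropic K)")

    @classmethod
    def full(cls) -> "ModelSpec":
        return cls(True, True, True, "full")

    @classmethod
    def isotropic(cls) -> "ModelSpec":
        return cls(True, False, True, "isotropic")

    @classmethod
    def no_mortality(cls) -> "ModelSpec":
        return cls(True, True, False, "no_mortality")

    @classmethod
    def isotropic_no_mortality(cls) -> "ModelSpec":
        return cls(True, False, False, "isotropic_no_mortality")

    @classmethod
    def intercept_only(cls) -> "ModelSpec":
        return cls(False, False, False, "intercept_only")

    @classmethod
    def all_nested(cls) -> list["ModelSpec"]:
        """The submodel lattice: full down to intercept-only."""
        return [
            cls.full(),
            cls.isotropic(),
            cls.no_mortality(),
            cls.isotropic_no_mortality(),
            cls.intercept_only(),
        ]

    @property
    def has_kernel(self) -> bool:
        return self.free_kx

    @property
    def packed_names(self) -> list[str]:
        names = ["beta"]
        if self.free_kx:
            names.append("log_Kx")
        if self.free_ky:
            names.append("log_Ky")
        if self.free_mu:
            names.append("log_mu")
        names.append("log_k")
        return names


def _nb_logpmf(y: np.ndarray, m: np.ndarray, k: float) -> np.ndarray:
    """log NB(y; mean m, size k), stable for tiny means."""
    m = np.clip(m, 1e-300, None)
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1.0)
        + k * (np.log(k) - np.log(k + m))
        + y * (np.log(m) - np.log(k + m))
    )


class EggDispersalModel:
    """Negative-binomial dispersal model bound to one survey's observations.

    Parameters
    ----------
    obs : DataFrame with columns ``t_hours, x_m, y_m, z_m, count, volume_l``
        Per-minute tow records in the drifter-centroid frame.
    vertical : VerticalConcentration
        The gridded vertical density C(z, t); every observation must fall
        inside its (z, t) span.
    spec : ModelSpec
        Which of Kx, Ky, mu are free.
    """

    def __init__(
        self,
        obs: pd.DataFrame,
        vertical: VerticalConcentration,
        spec: ModelSpec = ModelSpec.full(),
    ) -> None:
        obs = validate_observations(obs)
        self.obs = obs
        self.vertical = vertical
        self.spec = spec
        self.counts = obs["count"].to_numpy(dtype=float)
        self.volumes = obs["volume_l"].to_numpy(dtype=float)
        self.x = obs["x_m"].to_numpy(dtype=float)
        self.y = obs["y_m"].to_numpy(dtype=float)
        self.z = obs["z_m"].to_numpy(dtype=float)
        self.t = obs["t_hours"].to_numpy(dtype=float)
        if (self.t <= 0).any():
            raise ValueError("observations must be after the release (t > 0)")
        # raises if any observation falls outside the gridded (z, t) span
        self.cz = np.asarray(vertical.interp(self.z, self.t), dtype=float)
        self.nobs = len(obs)
        self._null_result: "EggDispersalResults | None" = None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, vertical: VerticalConcentration, spec: ModelSpec = ModelSpec.full()
    ) -> "EggDispersalModel":
        return cls(df, vertical, spec)

    # ---- likelihood -------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> dict[str, float]:
        vals = dict(zip(self.spec.packed_names, theta))
        out = {"beta": vals["beta"], "k": float(np.exp(vals["log_k"]))}
        if self.spec.free_kx:
            out["Kx"] = float(np.exp(vals["log_Kx"]))
            out["Ky"] = float(np.exp(vals["log_Ky"])) if self.spec.free_ky else out["Kx"]
        else:
            out["Kx"] = np.nan
            out["Ky"] = np.nan
        out["mu"] = float(np.exp(vals["log_mu"])) if self.spec.free_mu else 0.0
        return out

    def mean_counts(self, params: dict[str, float]) -> np.ndarray:
        """Expected counts per minute at the observation points."""
        ebeta = np.exp(params["beta"])
        if self.spec.has_kernel:
            Kx, Ky, mu = params["Kx"], params["Ky"], params["mu"]
            hor = np.exp(
                -(self.x**2) / (4.0 * Kx * self.t)
                - (self.y**2) / (4.0 * Ky * self.t)
                - mu * self.t
            ) / (4.0 * np.pi * self.t * np.sqrt(Kx * Ky))
            conc_per_l = ebeta * self.cz * hor * 1e-3
        else:
            conc_per_l = ebeta * 1e-3 * np.ones(self.nobs)
        return conc_per_l * self.volumes

    def neg_loglik(self, params: dict[str, float]) -> float:
        """-log L at the given natural-scale parameter values."""
        m = self.mean_counts(params)
        if not np.isfinite(m).all():
            return _PENALTY
        ll = _nb_logpmf(self.counts, m, params["k"]).sum()
        return float(-ll) if np.isfinite(ll) else _PENALTY

    def _nll_packed(self, theta: np.ndarray) -> float:
        return self.neg_loglik(self._unpack(theta))

    # ---- fitting ----------------------------------------------------

    def _start_values(self) -> np.ndarray:
        params = {"Kx": 1e4, "Ky": 1e4, "mu": 0.1, "k": 1.0, "beta": 0.0}
        # moment-match beta: scale unit-beta predictions to the observed total
        base = self.mean_counts(params)
        total = self.counts.sum()
        params["beta"] = float(np.log(max(total, 1.0) / max(base.sum(), 1e-300)))
        start = {"beta": params["beta"], "log_Kx": np.log(1e4), "log_Ky": np.log(1e4),
                 "log_mu": np.log(0.1), "log_k": 0.0}
        return np.array([start[n] for n in self.spec.packed_names])

    def _minimize(
        self, start: np.ndarray, fixed: dict[int, float] | None = None
    ) -> optimize.OptimizeResult:
        """L-BFGS-B on the packed vector, optionally with entries pinned."""
        fixed = fixed or {}
        free_idx = [i for i in range(start.size) if i not in fixed]
        theta0 = start.copy()
        for i, v in fixed.items():
            theta0[i] = v

        def obj(free_vals: np.ndarray) -> float:
            theta = theta0.copy()
            theta[free_idx] = free_vals
            return self._nll_packed(theta)

        bounds = [_BOUNDS[self.spec.packed_names[i]] for i in free_idx]
        res = optimize.minimize(
            obj,
            theta0[free_idx],
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = theta0.copy()
        theta[free_idx] = res.x
        res.theta_full = theta
        return res

    def fit(
        self,
        start: np.ndarray | dict[str, float] | None = None,
        n_starts: int = 5,
        seed: int = 0,
        jitter_sd: float = 0.7,
    ) -> "EggDispersalResults":
        """Maximize the likelihood with jittered multi-starts.

        Returns a results object even on non-convergence (flagged via
        ``converged``); never raises for optimizer failure.
        """
        if isinstance(start, dict):
            start = np.array([start[n] for n in self.spec.packed_names])
        theta0 = self._start_values() if start is None else np.asarray(start, dtype=float)
        rng = np.random.default_rng(seed)
        best = None
        for i in range(max(1, n_starts)):
            s = theta0 if i == 0 else theta0 + rng.normal(0.0, jitter_sd, theta0.size)
            s = np.clip(
                s,
                [_BOUNDS[n][0] for n in self.spec.packed_names],
                [_BOUNDS[n][1] for n in self.spec.packed_names],
            )
            try:
                res = self._minimize(s)
            except Exception:  # optimizer failure on one start is not fatal
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("all optimizer starts failed")
        grad = optimize.approx_fprime(best.x, lambda v: self._minimize_obj_at(best, v), 1e-6)
        grad_norm = float(np.max(np.abs(grad)))
        return EggDispersalResults(
            model=self,
            theta=best.theta_full,
            llf=-float(best.fun),
            converged=bool(best.success),
            grad_norm=grad_norm,
        )

    def _minimize_obj_at(self, res: optimize.OptimizeResult, free_vals: np.ndarray) -> float:
        theta = res.theta_full.copy()
        theta[: free_vals.size] = free_vals  # no fixing in top-level fits
        return self._nll_packed(theta)

    def null_model_result(self, **fit_kw) -> "EggDispersalResults":
        """Intercept-only fit on the same observations (cached)."""
        if self._null_result is None:
            null = EggDispersalModel(self.obs, self.vertical, ModelSpec.intercept_only())
            self._null_result = null.fit(**fit_kw)
        return self._null_result


@dataclass
class EggDispersalResults:
    """ML estimates, profile intervals and fit diagnostics."""

    model: EggDispersalModel
    theta: np.ndarray  # packed (log-scale) parameter vector at the optimum
    llf: float
    converged: bool
    grad_norm: float
    _profile_cache: dict = field(default_factory=dict, repr=False)

    # ---- point estimates --------------------------------------------

    @property
    def params(self) -> dict[str, float]:
        """Natural-scale estimates: beta, Kx, Ky (m^2 h^-1), mu (h^-1), k."""
        return self.model._unpack(self.theta)

    @property
    def n_params(self) -> int:
        return len(self.model.spec.packed_names)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.llf

    # ---- profile likelihood intervals -------------------------------

    def profile_interval(
        self, param: str, level: float = 0.95
    ) -> tuple[float, float]:
        """Profile-likelihood CI for a natural-scale parameter.

        Endpoints are where the profiled -log L rises chi^2_1(level)/2
        above its minimum, re-optimizing all other parameters at each
        profile point; the search runs on the packed (log) scale and the
        interval is returned on the natural scale.  An endpoint that hits
        the box bound is returned at the bound (one-sided interval).
        """
        key = (param, level)
        if key in self._profile_cache:
            return self._profile_cache[key]
        packed = {"beta": "beta", "Kx": "log_Kx", "Ky": "log_Ky", "mu": "log_mu", "k": "log_k"}
        if param not in packed or packed[param] not in self.model.spec.packed_names:
            raise ValueError(f"parameter {param!r} is not free in this model spec")
        j = self.model.spec.packed_names.index(packed[param])
        rise = float(stats.chi2.ppf(level, df=1) / 2.0)
        nll_min = -self.llf

        def pnll(val: float) -> float:
            res = self.model._minimize(self.theta, fixed={j: val})
            return float(res.fun)

        lo_b, hi_b = _BOUNDS[packed[param]]
        lo = _profile_root(pnll, self.theta[j], nll_min, rise, bound=lo_b, direction=-1)
        hi = _profile_root(pnll, self.theta[j], nll_min, rise, bound=hi_b, direction=+1)
        out = (lo, hi) if param == "beta" else (float(np.exp(lo)), float(np.exp(hi)))
        self._profile_cache[key] = out
        return out

    def conf_int(self, level: float = 0.95, params: Sequence[str] | None = None) -> pd.DataFrame:
        """Profile CIs for all free natural parameters as a DataFrame."""
        natural = {"log_Kx": "Kx", "log_Ky": "Ky", "log_mu": "mu", "log_k": "k", "beta": "beta"}
        names = params or [natural[n] for n in self.model.spec.packed_names]
        rows = {p: self.profile_interval(p, level) for p in names}
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    # ---- deviance ----------------------------------------------------

    def deviance(self) -> float:
        """2 * (saturated log L - model log L), at the model's own k-hat."""
        y = self.model.counts
        k = self.params["k"]
        ll_sat = float(_nb_logpmf(y, np.clip(y, 1e-300, None), k).sum())
        return 2.0 * (ll_sat - self.llf)

    def deviance_explained(self) -> float:
        """1 - deviance(model) / deviance(intercept-only null).

        Both deviances are evaluated at the model's own k-hat (the NB-GLM
        convention: a common dispersion makes the two deviances
        commensurable); the null mean is the ML constant-concentration
        fit with the volume exposure.
        """
        y = self.model.counts
        vol = self.model.volumes
        k = self.params["k"]

        def nll_const(log_c: float) -> float:
            return -float(_nb_logpmf(y, np.exp(log_c) * vol, k).sum())

        r = optimize.minimize_scalar(nll_const, bounds=(-60.0, 60.0), method="bounded")
        ll_null = -float(r.fun)
        ll_sat = float(_nb_logpmf(y, np.clip(y, 1e-300, None), k).sum())
        d0 = 2.0 * (ll_sat - ll_null)
        if d0 <= 0:
            raise ValueError("null deviance is zero; deviance explained undefined")
        return 1.0 - 2.0 * (ll_sat - self.llf) / d0

    # ---- presentation ------------------------------------------------

    def summary(self, conf_int: bool = False, level: float = 0.95) -> str:
        """Plain-text fit summary; ``conf_int=True`` adds profile CIs."""
        p = self.params
        spec = self.model.spec
        lines = [
            "Egg dispersal model (negative binomial ML)",
            f"  submodel: {spec.name}    nobs: {self.nobs}",
            f"  log-likelihood: {self.llf:.3f}    AIC: {self.aic:.3f}",
            f"  converged: {self.converged}    max|grad|: {self.grad_norm:.2e}",
            "",
            f"  {'param':<6} {'estimate':>12}" + (f" {'lower':>12} {'upper':>12}" if conf_int else ""),
        ]
        shown = ["beta"]
        if spec.free_kx:
            shown.append("Kx")
        if spec.free_ky:
            shown.append("Ky")
        if spec.free_mu:
            shown.append("mu")
        shown.append("k")
        for name in shown:
            row = f"  {name:<6} {p[name]:>12.5g}"
            if conf_int:
                lo, hi = self.profile_interval(name, level)
                row += f" {lo:>12.5g} {hi:>12.5g}"
            lines.append(row)
        if not spec.free_ky and spec.free_kx:
            lines.append("  (isotropic: Ky = Kx)")
        if not spec.free_mu:
            lines.append("  (mortality fixed at 0)")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs fitted expected counts along the tow (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model.mean_counts(self.params)
        ax.plot(self.model.t, self.model.counts, ".", ms=3, alpha=0.6, label="observed")
        ax.plot(self.model.t, m, "-", lw=1, label="expected")
        ax.set_xlabel("hours since release")
        ax.set_ylabel("eggs per minute")
        ax.legend()
        return ax


def _profile_root(
    pnll, x_hat: float, nll_min: float, rise: float, bound: float, direction: int
) -> float:
    """Find where the profiled -logL crosses nll_min + rise on one side."""
    target = nll_min + rise

    def g(x: float) -> float:
        return pnll(x) - target

    step = 0.25
    x_in = x_hat
    for _ in range(60):
        x_out = x_hat + direction * step
        if (direction < 0 and x_out <= bound) or (direction > 0 and x_out >= bound):
            x_out = bound
        if g(x_out) > 0:
            return float(optimize.brentq(g, min(x_in, x_out), max(x_in, x_out), xtol=1e-6))
        if x_out == bound:
            return float(bound)  # one-sided: profile never rises enough
        x_in = x_out
        step *= 2.0
    return float(bound)


def profile_interval_1d(
    f, x_hat: float, f_min: float, rise: float = PROFILE_RISE_95,
    lo_bound: float = -np.inf, hi_bound: float = np.inf,
) -> tuple[float, float]:
    """Likelihood-ratio interval of a 1-D objective: {x : f(x) <= f_min + rise}.

    Generic helper (no re-optimization); on a quadratic -logL of curvature
    1/sigma^2 it returns x_hat +/- sqrt(2*rise)*sigma, i.e. +/-1.96 sigma
    at the 95% rise.
    """
    lo = _profile_root(f, x_hat, f_min, rise, bound=lo_bound, direction=-1)
    hi = _profile_root(f, x_hat, f_min, rise, bound=hi_bound, direction=+1)
    return lo, hi


# ---- functional wrappers over the Model/Results objects ----------------


def nb_neg_loglik(
    values: dict[str, float],
    obs: pd.DataFrame,
    vertical: VerticalConcentration,
    spec: ModelSpec = ModelSpec.full(),
) -> float:
    """-log L at natural-scale values {beta, Kx, Ky, mu, k}."""
    return EggDispersalModel(obs, vertical, spec).neg_loglik(values)


def fit_ml(
    obs: pd.DataFrame,
    vertical: VerticalConcentration,
    spec: ModelSpec = ModelSpec.full(),
    **fit_kw,
) -> EggDispersalResults:
    """Fit by maximum likelihood; see :meth:`EggDispersalModel.fit`."""
    return EggDispersalModel(obs, vertical, spec).fit(**fit_kw)


def profile_interval(
    result: EggDispersalResults, param: str, level: float = 0.95
) -> tuple[float, float]:
    return result.profile_interval(param, level)


def deviance_explained(result: EggDispersalResults) -> float:
    return result.deviance_explained()


def model_selection_table(
    obs: pd.DataFrame,
    vertical: VerticalConcentration,
    specs: Sequence[ModelSpec] | None = None,
    **fit_kw,
) -> pd.DataFrame:
    """Fit the nested-submodel lattice and tabulate AIC.

    Returns one row per submodel with estimates, log-likelihood, AIC and
    delta-AIC relative to the best (lowest-AIC) submodel.
    """
    specs = list(specs) if specs is not None else ModelSpec.all_nested()
    rows = []
    for spec in specs:
        res = EggDispersalModel(obs, vertical, spec).fit(**fit_kw)
        p = res.params
        rows.append(
            {
                "model": spec.name,
                "n_params": res.n_params,
                "loglik": res.llf,
                "aic": res.aic,
                "converged": res.converged,
                "beta": p["beta"],
                "Kx": p["Kx"],
                "Ky": p["Ky"],
                "mu": p["mu"],
                "k": p["k"],
            }
        )
    tab = pd.DataFrame(rows)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab.sort_values("aic").reset_index(drop=True)
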