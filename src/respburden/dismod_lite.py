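"""Illness-death consistency meta-regression.

Takes all available datapoints on prevalence, incidence, remission, excess
mortality and cause-specific mortality jointly and forces a consistent set
of estimates: every predicted measure is derived from one underlying set
of age-gridded rates through the illness-death system, never a free
parameter.  The fit is a maximum-a-posteriori estimate in log-rate space
with Gaussian smoothness priors between adjacent age knots; posterior
draws come from the curvature (inverse-Hessian) approximation at the
optimum.

Covariates:
* study-level multiplicative covariates (e.g. self-reported diagnosis,
  health-service encounter source) scale a datapoint's predicted value and
  are divided out at prediction time, so predictions are on the
  reference-definition scale;
* a combined risk-exposure scalar enters incidence log-linearly;
* rescaled income enters excess mortality log-linearly with the
  coefficient constrained non-positive (case fatality falls with wealth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import yaml

from .drawcube import DrawCube
from .illness_death import (  # noqa: F401  (re-exported public surface)
    PrevalenceSolution,
    RateSet,
    solve_batch,
    solve_illness_death,
)

__all__ = [
    "RateSet",
    "PrevalenceSolution",
    "solve_illness_death",
    "derive_emr_datapoints",
    "DismodConfig",
    "MetaRegressionFit",
    "fit_consistent",
    "predict",
]

log = logging.getLogger(__name__)

MEASURES = ("prevalence", "incidence", "remission", "emr", "csmr")


def _stack_cols(x: np.ndarray) -> np.ndarray:
    """(S, A, G) -> (A, S*G) with column index s*G + g."""
    S, A, G = x.shape
    return np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(A, S * G)


def derive_emr_datapoints(
    csmr_points: pd.DataFrame, prevalence_points: pd.DataFrame
) -> pd.DataFrame:
    """Excess-mortality datapoints as CSMR / prevalence for matched cells.

    Both inputs need columns (location, year, sex, age_start, age_end,
    mean, standard_error); pairs are matched on the key columns.  The
    standard error follows from the delta method for a ratio of
    independent estimates.  Pairs with non-positive prevalence are skipped
    with a logged reason.
    """
    keys = ["location", "year", "sex", "age_start", "age_end"]
    merged = csmr_points.merge(
        prevalence_points, on=keys, suffixes=("_csmr", "_prev")
    )
    bad = merged["mean_prev"] <= 0
    for _, row in merged[bad].iterrows():
        log.info("skipping EMR datapoint with prevalence <= 0 at %s",
                 {k: row[k] for k in keys})
    merged = merged[~bad].copy()
    c, p = merged["mean_csmr"], merged["mean_prev"]
    sc, sp = merged["standard_error_csmr"], merged["standard_error_prev"]
    emr = c / p
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.sqrt((sc / c.replace(0, np.nan)) ** 2 + (sp / p) ** 2)
    se = np.where(c > 0, emr * rel.fillna(0.0), sp * 0 + sc / p)
    out = merged[keys].copy()
    out["measure"] = "emr"
    out["mean"] = emr
    out["standard_error"] = se
    out["definition"] = "reference"
    return out


@dataclass
class DismodConfig:
    """Knots, priors, and covariate wiring of the consistency fit."""

    knots: tuple = (0, 5, 15, 30, 45, 60, 75, 90)
    age_max: int = 100
    n_substeps: int = 2
    remission: str = "zero"  # "zero" (chronic, incurable) or "fit"
    smoothness_sd: dict = field(
        default_factory=lambda: {"i": 1.0, "r": 1.0, "f": 1.0}
    )
    study_covariates: tuple = ()  # definition tags receiving multipliers
    beta_prior_sd: float = 2.0
    log_rate_bounds: tuple = (-20.0, 3.0)
    # transition rates above this are epidemiologically meaningless here and
    # would destabilise the fixed-step integrator during line search
    rate_cap: float = 2.0
    maxiter: int = 200
    max_newton: int = 40
    gtol: float = 1e-6

    def __post_init__(self):
        if self.remission not in ("zero", "fit"):
            raise ValueError("remission must be 'zero' or 'fit'")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")


class _Problem:
    """Pre-indexed data structures for fast batched objective evaluation."""

    def __init__(self, datapoints, covariates, m_background, config):
        self.config = config
        K = len(config.knots)
        A = config.age_max
        self.K, self.A = K, A

        # parameter layout
        names = [f"log_i[{k}]" for k in config.knots]
        self.sl_i = slice(0, K)
        pos = K
        if config.remission == "fit":
            self.sl_r = slice(pos, pos + K)
            names += [f"log_r[{k}]" for k in config.knots]
            pos += K
        else:
            self.sl_r = None
        self.sl_f = slice(pos, pos + K)
        names += [f"log_f[{k}]" for k in config.knots]
        pos += K
        self.sl_study = slice(pos, pos + len(config.study_covariates))
        names += [f"beta_study[{t}]" for t in config.study_covariates]
        pos += len(config.study_covariates)
        self.idx_risk = pos
        self.idx_income = pos + 1
        names += ["beta_risk", "beta_income"]
        self.n_params = pos + 2
        self.names = names

        # knot -> yearly expansion
        years = np.arange(A, dtype=float)
        self.knot_of_year = np.clip(
            np.searchsorted(np.asarray(config.knots, float), years, side="right") - 1,
            0, K - 1,
        )

        # groups = unique (location, year) with covariates
        dp = datapoints.reset_index(drop=True)
        gkeys = dp[["location", "year"]].drop_duplicates().reset_index(drop=True)
        self.groups = gkeys
        gindex = {tuple(row): g for g, row in enumerate(gkeys.itertuples(index=False))}
        self.group_of_dp = np.array(
            [gindex[(row.location, row.year)] for row in dp.itertuples(index=False)]
        )
        cov = covariates.set_index(["location", "year"])
        missing = [t for t in map(tuple, gkeys.to_numpy()) if t not in cov.index]
        if missing:
            raise ValueError(f"missing covariates for cells: {missing[:3]}")
        self.risk_scalar = np.array(
            [cov.loc[t, "risk_scalar"] for t in map(tuple, gkeys.to_numpy())]
        )
        self.ldi = np.array(
            [cov.loc[t, "ldi"] for t in map(tuple, gkeys.to_numpy())]
        )
        self.G = len(gkeys)

        # background mortality per (year, group)
        m = np.asarray(m_background, dtype=float)
        if m.ndim == 1:
            m = np.tile(m[:, None], (1, self.G))
        if m.shape != (A, self.G):
            raise ValueError(f"m_background shape {m.shape} != {(A, self.G)}")
        self.m = m

        # fine grid bookkeeping
        n_sub = config.n_substeps
        self.fine_ages = np.linspace(0.0, A, A * n_sub + 1)
        self.year_of_fine = np.minimum(self.fine_ages.astype(int), A - 1)

        # per-datapoint band-average weights over the fine grid (sparse:
        # each row touches only the grid points inside its age band)
        import scipy.sparse

        n_dp = len(dp)
        rows, cols, vals = [], [], []
        for d, row in enumerate(dp.itertuples(index=False)):
            mask = (self.fine_ages >= row.age_start) & (self.fine_ages < row.age_end)
            if not mask.any():
                mask = np.isclose(self.fine_ages, row.age_start)
            idx = np.where(mask)[0]
            rows += [d] * len(idx)
            cols += list(idx)
            vals += [1.0 / len(idx)] * len(idx)
        self.W = scipy.sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_dp, len(self.fine_ages))
        )

        self.measure = dp["measure"].to_numpy()
        unknown = set(self.measure) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        self.obs = dp["mean"].to_numpy(dtype=float)
        self.se = dp["standard_error"].to_numpy(dtype=float)
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be > 0")
        tag_idx = {t: j for j, t in enumerate(config.study_covariates)}
        defs = dp.get("definition", pd.Series(["reference"] * n_dp))
        self.study_of_dp = np.array([tag_idx.get(t, -1) for t in defs])
        self.dp = dp

    # -- batched evaluation ------------------------------------------------

    def _grids(self, thetas: np.ndarray):
        """Rate grids for a stack of parameter vectors.

        Returns yearly-rate arrays of shape (A, S*G) ordered with group
        fastest, plus the stack size S.
        """
        S = thetas.shape[0]
        cfg = self.config
        li = thetas[:, self.sl_i][:, self.knot_of_year]  # (S, A)
        lf = thetas[:, self.sl_f][:, self.knot_of_year]
        if self.sl_r is not None:
            lr = thetas[:, self.sl_r][:, self.knot_of_year]
        else:
            lr = np.full_like(li, -np.inf)
        b_risk = thetas[:, self.idx_risk]
        b_inc = thetas[:, self.idx_income]
        cap = self.config.rate_cap
        # (S, A, G)
        i = np.exp(li[:, :, None] + (b_risk[:, None] * self.risk_scalar[None, :])[:, None, :])
        f = np.exp(lf[:, :, None] + (b_inc[:, None] * self.ldi[None, :])[:, None, :])
        r = np.exp(lr)[:, :, None] * np.ones((1, 1, self.G))
        i, f, r = np.minimum(i, cap), np.minimum(f, cap), np.minimum(r, cap)
        m = np.broadcast_to(self.m[None], (S, self.A, self.G))
        # column order: setting-major, group fastest (column = g + G*s)
        return (_stack_cols(i), _stack_cols(r), _stack_cols(f), _stack_cols(m), S)

    def predictions(self, thetas: np.ndarray) -> np.ndarray:
        """Predicted values for every datapoint under each parameter
        setting; shape (S, n_dp)."""
        i_c, r_c, f_c, m_c, S = self._grids(thetas)
        _, Sv, Cv = solve_batch(i_c, r_c, f_c, m_c, n_substeps=self.config.n_substeps)
        alive = Sv + Cv
        p = np.where(alive > 0, Cv / np.where(alive > 0, alive, 1.0), 0.0)
        fine = {
            "prevalence": p,
            "incidence": i_c[self.year_of_fine, :],
            "remission": r_c[self.year_of_fine, :],
            "emr": f_c[self.year_of_fine, :],
        }
        fine["csmr"] = p * fine["emr"]
        n_dp = len(self.obs)
        preds = np.empty((S, n_dp))
        col = self.group_of_dp[None, :] + self.G * np.arange(S)[:, None]  # (S, n_dp)
        for meas in np.unique(self.measure):
            sel = np.where(self.measure == meas)[0]
            band = np.asarray(self.W[sel] @ fine[meas])  # (n_sel, G*S)
            preds[:, sel] = band[np.arange(len(sel))[:, None], col[:, sel].T].T
        mult = np.ones((S, n_dp))
        has = self.study_of_dp >= 0
        if has.any():
            beta = thetas[:, self.sl_study]
            mult[:, has] = np.exp(beta[:, self.study_of_dp[has]])
        return preds * mult

    def nll(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        preds = self.predictions(thetas)
        resid = (self.obs[None, :] - preds) / self.se[None, :]
        out = 0.5 * (resid**2).sum(axis=1)
        cfg = self.config
        for sl, meas in ((self.sl_i, "i"), (self.sl_r, "r"), (self.sl_f, "f")):
            if sl is None:
                continue
            diffs = np.diff(thetas[:, sl], axis=1)
            out += 0.5 * (diffs**2).sum(axis=1) / cfg.smoothness_sd[meas] ** 2
        betas = thetas[:, self.sl_study.start:]
        out += 0.5 * (betas**2).sum(axis=1) / cfg.beta_prior_sd**2
        return np.nan_to_num(out, nan=1e12, posinf=1e12)

    def nll_scalar(self, theta: np.ndarray) -> float:
        return float(self.nll(theta[None, :])[0])

    def grad(self, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Forward-difference gradient via one batched evaluation."""
        P = self.n_params
        thetas = np.vstack([theta[None, :], theta[None, :] + h * np.eye(P)])
        vals = self.nll(thetas)
        return (vals[1:] - vals[0]) / h

    def prior_matrix(self) -> np.ndarray:
        """Hessian of the (quadratic) priors: smoothness differences between
        adjacent knots plus ridge priors on the covariate coefficients."""
        P = self.n_params
        M = np.zeros((P, P))
        cfg = self.config
        for sl, meas in ((self.sl_i, "i"), (self.sl_r, "r"), (self.sl_f, "f")):
            if sl is None:
                continue
            K = sl.stop - sl.start
            D = np.diff(np.eye(K), axis=0)
            M[sl, sl] += D.T @ D / cfg.smoothness_sd[meas] ** 2
        beta_start = self.sl_study.start
        M[beta_start:, beta_start:] += np.eye(P - beta_start) / cfg.beta_prior_sd**2
        return M

    def jacobian(self, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Forward-difference Jacobian of predictions, (n_dp, P), via one
        batched evaluation."""
        P = self.n_params
        thetas = np.vstack([theta[None, :], theta[None, :] + h * np.eye(P)])
        preds = self.predictions(thetas)
        return (preds[1:] - preds[0]).T / h

    def gauss_newton_state(self, theta: np.ndarray):
        """(nll, gradient, Gauss-Newton Hessian) at theta."""
        J = self.jacobian(theta)
        pred = self.predictions(theta[None, :])[0]
        w = 1.0 / self.se**2
        resid = pred - self.obs
        Pm = self.prior_matrix()
        grad = J.T @ (w * resid) + Pm @ theta
        H = (J.T * w) @ J + Pm
        return self.nll_scalar(theta), grad, H


@dataclass
class MetaRegressionFit:
    """MAP fit plus curvature-based posterior draws."""

    config: DismodConfig
    problem: _Problem = field(repr=False)
    theta_map: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    draws: np.ndarray = field(repr=False)  # (n_draws, n_params)
    convergence: dict = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        return self.problem.names

    def rate_set(self, theta: np.ndarray | None = None) -> RateSet:
        th = self.theta_map if theta is None else theta
        pr = self.problem
        K = pr.K
        r = (np.exp(th[pr.sl_r]) if pr.sl_r is not None else np.zeros(K))
        return RateSet(
            knots=np.asarray(self.config.knots, float),
            i=np.exp(th[pr.sl_i]),
            r=r,
            f=np.exp(th[pr.sl_f]),
            m=pr.m.mean(axis=1)[
                np.clip(np.asarray(self.config.knots, int), 0, pr.A - 1)
            ],
        )

    def multipliers(self) -> dict[str, float]:
        th = self.theta_map[self.problem.sl_study]
        return {
            tag: float(np.exp(b))
            for tag, b in zip(self.config.study_covariates, th)
        }

    @property
    def beta_risk(self) -> float:
        return float(self.theta_map[self.problem.idx_risk])

    @property
    def beta_income(self) -> float:
        return float(self.theta_map[self.problem.idx_income])

    def predict_datapoints(self, theta: np.ndarray | None = None) -> np.ndarray:
        th = self.theta_map if theta is None else theta
        return self.problem.predictions(th[None, :])[0]

    def report(self) -> dict:
        return {
            "knots": list(self.config.knots),
            "incidence": [float(x) for x in np.exp(self.theta_map[self.problem.sl_i])],
            "excess_mortality": [
                float(x) for x in np.exp(self.theta_map[self.problem.sl_f])
            ],
            "remission": (
                [float(x) for x in np.exp(self.theta_map[self.problem.sl_r])]
                if self.problem.sl_r is not None else "fixed at 0"
            ),
            "multipliers": self.multipliers(),
            "beta_risk": self.beta_risk,
            "beta_income": self.beta_income,
            "convergence": self.convergence,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.report(), fh, sort_keys=False)


def _initial_theta(problem: _Problem) -> np.ndarray:
    """Crude data-driven starting values.

    Incidence knots start from the age gradient of the cumulative hazard
    implied by mean prevalence per age band (-ln(1-p) under the no-remission,
    no-differential-mortality limit); excess mortality starts from EMR band
    means; remission from remission datapoint means.
    """
    dp = problem.dp
    theta = np.zeros(problem.n_params)
    knots = np.asarray(problem.config.knots, dtype=float)
    edges = np.append(knots, problem.config.age_max)

    prev = dp[dp["measure"] == "prevalence"].copy()
    if len(prev):
        prev["age_mid"] = (prev["age_start"] + prev["age_end"]) / 2
        prev_by_age = prev.groupby("age_mid")["mean"].mean()
        ages = prev_by_age.index.to_numpy()
        H = -np.log1p(-np.clip(prev_by_age.to_numpy(), 0.0, 0.99))
        H_at = np.interp(edges, ages, H)
        i0 = np.maximum(np.diff(H_at) / np.diff(edges), 1e-7)
        theta[problem.sl_i] = np.log(i0)
    else:
        theta[problem.sl_i] = np.log(1e-4)

    emr = dp[dp["measure"].isin(["emr"])]
    f0 = np.full(problem.K, 0.01)
    if len(emr):
        mids = ((emr["age_start"] + emr["age_end"]) / 2).to_numpy()
        for k in range(problem.K):
            sel = (mids >= edges[k]) & (mids < edges[k + 1])
            if sel.any():
                f0[k] = max(float(emr["mean"].to_numpy()[sel].mean()), 1e-6)
        # fill empty knots from nearest informed neighbour
        informed = np.where(f0 != 0.01)[0]
        if len(informed):
            for k in range(problem.K):
                if f0[k] == 0.01:
                    f0[k] = f0[informed[np.argmin(np.abs(informed - k))]]
    theta[problem.sl_f] = np.log(f0)

    if problem.sl_r is not None:
        rem = dp[dp["measure"] == "remission"]["mean"]
        r0 = max(float(rem.mean()), 1e-4) if len(rem) else 0.02
        theta[problem.sl_r] = np.log(r0)
    return theta


def fit_consistent(
    datapoints: pd.DataFrame,
    covariates: pd.DataFrame,
    m_background: np.ndarray,
    config: DismodConfig | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> MetaRegressionFit:
    """MAP fit of the consistency model with curvature-based draws.

    Parameters
    ----------
    datapoints
        Columns (measure, location, year, sex, age_start, age_end, mean,
        standard_error, definition).  Measures: prevalence, incidence,
        remission, emr, csmr.
    covariates
        Per (location, year): ``risk_scalar`` (combined risk exposure,
        enters incidence) and ``ldi`` (rescaled income, enters excess
        mortality with a non-positive coefficient).
    m_background
        Background mortality per 1-year age, shape (age_max,) shared or
        (age_max, n_groups) per fitted location-year.
    """
    if config is None:
        config = DismodConfig()
    if not (datapoints["measure"] == "prevalence").any():
        raise ValueError("need at least one prevalence datapoint")
    problem = _Problem(datapoints, covariates, m_background, config)
    theta0 = _initial_theta(problem)
    lo, hi = config.log_rate_bounds
    bounds = []
    for name in problem.names:
        if name.startswith("log_"):
            bounds.append((lo, hi))
        elif name == "beta_income":
            bounds.append((-10.0, 0.0))  # case fatality decreases with wealth
        else:
            bounds.append((-10.0, 10.0))
    res = scipy.optimize.minimize(
        problem.nll_scalar,
        theta0,
        jac=problem.grad,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": config.maxiter, "maxfun": 5 * config.maxiter,
                 "ftol": 1e-12, "gtol": config.gtol},
    )

    # Gauss-Newton / Levenberg-Marquardt polish: the warm-started quadratic
    # approximation converges in a handful of steps where L-BFGS crawls
    # through the ill-conditioned smoothness-prior valley
    lo_b = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])
    theta = np.clip(res.x, lo_b, hi_b)
    nll, grad, H = problem.gauss_newton_state(theta)
    lam = 1e-3
    n_newton = 0
    trace = [float(nll)]
    for _ in range(config.max_newton):
        free = ~(((theta <= lo_b + 1e-12) & (grad > 0))
                 | ((theta >= hi_b - 1e-12) & (grad < 0)))
        gmax = float(np.max(np.abs(grad[free]))) if free.any() else 0.0
        if gmax < config.gtol * (1.0 + abs(nll)):
            break
        step = np.zeros_like(theta)
        Hf = H[np.ix_(free, free)] + lam * np.eye(int(free.sum()))
        step[free] = np.linalg.solve(Hf, -grad[free])
        new_theta = np.clip(theta + step, lo_b, hi_b)
        new_nll = problem.nll_scalar(new_theta)
        if new_nll < nll - 1e-12:
            theta, nll = new_theta, new_nll
            lam = max(lam / 3.0, 1e-8)
            _, grad, H = problem.gauss_newton_state(theta)
            n_newton += 1
            trace.append(float(nll))
        else:
            lam *= 10.0
            if lam > 1e8:
                break
    gnorm = float(np.max(np.abs(grad)))
    free = ~(((theta <= lo_b + 1e-12) & (grad > 0))
             | ((theta >= hi_b - 1e-12) & (grad < 0)))
    gnorm_free = float(np.max(np.abs(grad[free]))) if free.any() else 0.0
    converged = gnorm_free < max(1e-2, 1e-3 * (1.0 + abs(nll)))
    convergence = {"success": bool(converged), "n_lbfgs": int(res.nit),
                   "n_newton": n_newton, "grad_norm": gnorm_free,
                   "nll": float(nll)}
    if not converged:
        raise RuntimeError(
            f"consistency fit did not converge: grad_norm={gnorm_free:.3g}, "
            f"nll trace={[round(v, 3) for v in trace[-6:]]}"
        )

    # posterior covariance from the Gauss-Newton curvature at the optimum
    H = 0.5 * (H + H.T)
    evals, evecs = np.linalg.eigh(H)
    evals = np.clip(evals, 1e-6, None)
    cov = (evecs / evals) @ evecs.T
    rng = np.random.default_rng(seed)
    L = evecs * np.sqrt(1.0 / evals)
    z = rng.standard_normal((n_draws, problem.n_params))
    draws = theta[None, :] + z @ L.T
    draws[:, problem.idx_income] = np.minimum(draws[:, problem.idx_income], 0.0)
    for sl in (problem.sl_i, problem.sl_r, problem.sl_f):
        if sl is not None:
            draws[:, sl] = np.clip(draws[:, sl], lo, hi)
    return MetaRegressionFit(
        config=config, problem=problem, theta_map=theta, cov=cov,
        draws=draws, convergence=convergence,
    )


def predict(
    fit: MetaRegressionFit,
    table: pd.DataFrame,
    age_bounds: list[tuple[float, float]],
    n_draws: int | None = None,
    m_background: np.ndarray | None = None,
) -> dict[str, DrawCube]:
    """Prevalence and incidence draws for requested location-years.

    ``table`` needs columns (location, year, risk_scalar, ldi).  Study
    multipliers are not applied: predictions are on the reference
    definition scale.  Each output draw is the illness-death-consistent
    solution of that draw's rates.
    """
    for colname in ("risk_scalar", "ldi"):
        if colname not in table.columns:
            raise ValueError(f"missing covariate column '{colname}'")
        if table[colname].isna().any():
            bad = table[table[colname].isna()].head(3)
            raise ValueError(f"missing covariate '{colname}' for cells:\n{bad}")
    pr = fit.problem
    cfg = fit.config
    draws = fit.draws if n_draws is None else fit.draws[:n_draws]
    D = len(draws)
    G = len(table)
    A = cfg.age_max
    rs = table["risk_scalar"].to_numpy()
    ldi = table["ldi"].to_numpy()
    if m_background is None:
        m_year = pr.m.mean(axis=1)
    else:
        m_year = np.asarray(m_background, dtype=float)

    li = draws[:, pr.sl_i][:, pr.knot_of_year]  # (D, A)
    lf = draws[:, pr.sl_f][:, pr.knot_of_year]
    if pr.sl_r is not None:
        r_year = np.exp(draws[:, pr.sl_r][:, pr.knot_of_year])
    else:
        r_year = np.zeros((D, A))
    b_risk = draws[:, pr.idx_risk]
    b_inc = draws[:, pr.idx_income]

    i = np.exp(li[:, :, None] + (b_risk[:, None] * rs[None, :])[:, None, :])  # (D,A,G)
    f = np.exp(lf[:, :, None] + (b_inc[:, None] * ldi[None, :])[:, None, :])
    r = np.repeat(r_year[:, :, None], G, axis=2)
    if m_year.ndim == 1:
        m = np.broadcast_to(m_year[None, :, None], (D, A, G))
    else:  # (A, G) per-group background mortality
        m = np.broadcast_to(m_year[None, :, :], (D, A, G))

    fine_ages, Sv, Cv = solve_batch(
        _stack_cols(i), _stack_cols(r), _stack_cols(f),
        _stack_cols(np.ascontiguousarray(m)),
        n_substeps=cfg.n_substeps,
    )
    alive = Sv + Cv
    p = np.where(alive > 0, Cv / np.where(alive > 0, alive, 1.0), 0.0)
    year_of_fine = np.minimum(fine_ages.astype(int), A - 1)
    i_fine = _stack_cols(i)[year_of_fine, :]

    keys = []
    p_vals = np.empty((len(age_bounds) * G, D))
    i_vals = np.empty_like(p_vals)
    row = 0
    for g in range(G):
        cols = g + G * np.arange(D)
        for a0, a1 in age_bounds:
            mask = (fine_ages >= a0) & (fine_ages < a1)
            keys.append(
                {"location": table.iloc[g]["location"],
                 "year": table.iloc[g]["year"], "age_start": a0, "age_end": a1}
            )
            p_vals[row] = p[np.ix_(mask, cols)].mean(axis=0)
            i_vals[row] = i_fine[np.ix_(mask, cols)].mean(axis=0)
            row += 1
    keys = pd.DataFrame(keys)
    return {
        "prevalence": DrawCube(keys, p_vals),
        "incidence": DrawCube(keys, i_vals),
    }
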