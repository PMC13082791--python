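"""Bayesian hierarchical mixed-effects model of estimation responses.

Responses of subject s to number x in condition c are modeled as

    xhat_sic | x ~ N(m_sc(x), sigma_sc(x)^2),
    m_sc(x) ~ N(m_0c(x), tau^2),
    ln sigma_sc(x) ~ N(ln sigma_0c(x), nu^2),

with hyperpriors m_0c(x) ~ N(x, 20^2), sigma_0c(x) ~ N+(7, 7^2),
tau ~ N+(5, 10^2) and nu ~ N+(5, 10^2) (N+ is the normal truncated to
positive values).  The condition-level fixed effects m_0c(x) and
sigma_0c(x) summarize the population mean response and response
variability per presented number, shrinking per-subject estimates toward
them.

Parameters exist only for (condition, number) cells actually present in
the data, and subject-level parameters only for cells the subject saw.
Sampling uses Metropolis-within-Gibbs: the means are conjugate Gaussian
updates; the scales and hyper-sds use elementwise random-walk
Metropolis-Hastings on the log scale, with step sizes adapted during
warmup only (so the post-warmup chain targets the exact posterior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "HierarchicalModel",
    "SamplerConfig",
    "log_posterior",
    "sample_posterior",
    "simulate_from_model",
]

# hyperprior constants (means / sds)
M0_PRIOR_SD = 20.0
S0_PRIOR = (7.0, 7.0)
TAU_PRIOR = (5.0, 10.0)
NU_PRIOR = (5.0, 10.0)


def _log_norm(x, mean, sd):
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _log_halfnorm(x, mean, sd):
    """Log density of N(mean, sd^2) truncated to x > 0 (renormalized)."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        _log_norm(x, mean, sd) - np.log(norm.sf(-mean / sd)),
        -np.inf,
    )
    return out


@dataclass
class SamplerConfig:
    chains: int = 4
    draws: int = 500
    warmup: int = 500
    seed: int = 0
    thin: int = 1


class HierarchicalModel:
    """Indexing and sufficient statistics for the hierarchical model."""

    def __init__(self, table: pd.DataFrame):
        req = {"subject", "condition", "x", "response"}
        if not req.issubset(table.columns):
            raise ValueError(f"table must have columns {sorted(req)}")
        cells = (
            table.groupby(["condition", "x"], sort=True).size().index.to_list()
        )
        self.cells = cells  # list of (condition, x)
        self.cell_index = {cx: i for i, cx in enumerate(cells)}
        self.P = len(cells)
        self.cell_x = np.array([x for _, x in cells], dtype=float)
        g = table.groupby(["subject", "condition", "x"], sort=True)["response"]
        agg = g.agg(["size", "sum", lambda v: np.sum(np.asarray(v, float) ** 2)])
        agg.columns = ["n", "s1", "s2"]
        agg = agg.reset_index()
        self.Q = len(agg)
        self.q_cell = np.array(
            [self.cell_index[(c, x)] for c, x in zip(agg["condition"], agg["x"])]
        )
        self.q_n = agg["n"].to_numpy(dtype=float)
        self.q_s1 = agg["s1"].to_numpy(dtype=float)
        self.q_s2 = agg["s2"].to_numpy(dtype=float)
        self.N = int(self.q_n.sum())

    # ---------------- density ----------------

    def log_posterior(self, params: dict) -> float:
        """Joint log density; -inf outside the valid domain.

        The density is taken with respect to (m0, sigma0, m, ln sigma,
        tau, nu): subject-level scales enter through the normal law of
        their logarithm, exactly as the model is stated.
        """
        m0 = np.asarray(params["m0"], dtype=float)
        s0 = np.asarray(params["sigma0"], dtype=float)
        m = np.asarray(params["m"], dtype=float)
        ls = np.asarray(params["log_sigma"], dtype=float)
        tau = float(params["tau"])
        nu = float(params["nu"])
        if np.any(s0 <= 0) or tau <= 0 or nu <= 0:
            return -np.inf
        sig = np.exp(ls)
        # response likelihood from sufficient statistics
        ss = self.q_s2 - 2 * m * self.q_s1 + self.q_n * m**2
        lik = np.sum(
            -0.5 * self.q_n * np.log(2 * np.pi)
            - self.q_n * ls
            - 0.5 * ss / sig**2
        )
        lp = lik
        lp += np.sum(_log_norm(m, m0[self.q_cell], tau))
        lp += np.sum(_log_norm(ls, np.log(s0[self.q_cell]), nu))
        lp += np.sum(_log_norm(m0, self.cell_x, M0_PRIOR_SD))
        lp += np.sum(_log_halfnorm(s0, *S0_PRIOR))
        lp += float(_log_halfnorm(tau, *TAU_PRIOR))
        lp += float(_log_halfnorm(nu, *NU_PRIOR))
        return float(lp)

    # ---------------- sampler ----------------

    def _init_params(self, rng: np.random.Generator) -> dict:
        mean_q = self.q_s1 / self.q_n
        var_q = np.maximum(self.q_s2 / self.q_n - mean_q**2, 1.0)
        m0 = np.zeros(self.P)
        s0 = np.zeros(self.P)
        counts = np.bincount(self.q_cell, minlength=self.P)
        np.add.at(m0, self.q_cell, mean_q)
        np.add.at(s0, self.q_cell, np.sqrt(var_q))
        m0 /= counts
        s0 = np.maximum(s0 / counts, 0.5)
        def jit(n):
            return 0.1 * rng.standard_normal(n)

        return {
            "m0": m0 + jit(self.P),
            "sigma0": s0 * np.exp(0.05 * rng.standard_normal(self.P)),
            "m": mean_q + jit(self.Q),
            "log_sigma": 0.5 * np.log(var_q) + 0.05 * rng.standard_normal(self.Q),
            "tau": 3.0,
            "nu": 0.5,
        }

    def _sweep(self, p: dict, steps: dict, rng: np.random.Generator,
               adapt: float | None) -> None:
        n, s1 = self.q_n, self.q_s1
        sig2 = np.exp(2 * p["log_sigma"])
        tau2, nu2 = p["tau"] ** 2, p["nu"] ** 2
        # conjugate update: subject means
        prec = n / sig2 + 1.0 / tau2
        mean = (s1 / sig2 + p["m0"][self.q_cell] / tau2) / prec
        p["m"] = mean + rng.standard_normal(self.Q) / np.sqrt(prec)
        # conjugate update: cell-level means
        counts = np.bincount(self.q_cell, minlength=self.P)
        msum = np.bincount(self.q_cell, weights=p["m"], minlength=self.P)
        prec0 = counts / tau2 + 1.0 / M0_PRIOR_SD**2
        mean0 = (msum / tau2 + self.cell_x / M0_PRIOR_SD**2) / prec0
        p["m0"] = mean0 + rng.standard_normal(self.P) / np.sqrt(prec0)

        def cell_loglik(ls):
            ss = self.q_s2 - 2 * p["m"] * s1 + n * p["m"] ** 2
            return -n * ls - 0.5 * ss / np.exp(2 * ls)

        # elementwise MH: subject log-scales
        ls = p["log_sigma"]
        prop = ls + steps["ls"] * rng.standard_normal(self.Q)
        ls0c = np.log(p["sigma0"])[self.q_cell]
        logr = (
            cell_loglik(prop) - cell_loglik(ls)
            + _log_norm(prop, ls0c, p["nu"]) - _log_norm(ls, ls0c, p["nu"])
        )
        acc = np.log(rng.random(self.Q)) < logr
        p["log_sigma"] = np.where(acc, prop, ls)
        if adapt is not None:
            steps["ls"] *= np.exp(adapt * (acc.mean() - 0.44))
        # elementwise MH: cell scales sigma0 (proposal on log sigma0;
        # the Jacobian log sigma0 converts the N+ density to that scale)
        l0 = np.log(p["sigma0"])
        prop0 = l0 + steps["l0"] * rng.standard_normal(self.P)
        lsum = np.bincount(self.q_cell, weights=p["log_sigma"], minlength=self.P)
        lsq = np.bincount(self.q_cell, weights=p["log_sigma"] ** 2, minlength=self.P)

        def s0_target(l0v):
            # sum over cells' subjects of N(log sigma_q; l0v, nu^2) + prior + Jacobian
            ss = lsq - 2 * l0v * lsum + counts * l0v**2
            return (
                -0.5 * ss / nu2
                + _log_halfnorm(np.exp(l0v), *S0_PRIOR)
                + l0v
            )

        logr0 = s0_target(prop0) - s0_target(l0)
        acc0 = np.log(rng.random(self.P)) < logr0
        l0 = np.where(acc0, prop0, l0)
        p["sigma0"] = np.exp(l0)
        if adapt is not None:
            steps["l0"] *= np.exp(adapt * (acc0.mean() - 0.44))
        # joint translation moves along the funnel directions: shift a
        # cell's fixed effect together with all its subject effects, so the
        # cell level keeps mixing even when tau or nu collapse toward zero
        sig2 = np.exp(2 * p["log_sigma"])
        delta = steps["tm"] * rng.standard_normal(self.P)
        dq = delta[self.q_cell]
        dlik = (dq * s1 - n * p["m"] * dq - 0.5 * n * dq**2) / sig2
        dlik_p = np.bincount(self.q_cell, weights=dlik, minlength=self.P)
        m0p = p["m0"] + delta
        dprior = _log_norm(m0p, self.cell_x, M0_PRIOR_SD) - _log_norm(
            p["m0"], self.cell_x, M0_PRIOR_SD
        )
        accm = np.log(rng.random(self.P)) < dlik_p + dprior
        p["m0"] = np.where(accm, m0p, p["m0"])
        p["m"] = p["m"] + np.where(accm[self.q_cell], dq, 0.0)
        if adapt is not None:
            steps["tm"] *= np.exp(adapt * (accm.mean() - 0.3))
        delta = steps["ts"] * rng.standard_normal(self.P)
        dq = delta[self.q_cell]
        ss = self.q_s2 - 2 * p["m"] * s1 + n * p["m"] ** 2
        sig2 = np.exp(2 * p["log_sigma"])
        dlik = -n * dq - 0.5 * (ss / sig2) * np.expm1(-2 * dq)
        dlik_p = np.bincount(self.q_cell, weights=dlik, minlength=self.P)
        l0 = np.log(p["sigma0"])
        l0p = l0 + delta
        dprior = (
            _log_halfnorm(np.exp(l0p), *S0_PRIOR) + l0p
            - _log_halfnorm(p["sigma0"], *S0_PRIOR) - l0
        )
        accs = np.log(rng.random(self.P)) < dlik_p + dprior
        p["sigma0"] = np.exp(np.where(accs, l0p, l0))
        p["log_sigma"] = p["log_sigma"] + np.where(accs[self.q_cell], dq, 0.0)
        if adapt is not None:
            steps["ts"] *= np.exp(adapt * (accs.mean() - 0.3))
        # scalar MH: tau and nu (log-scale random walk)
        dev_m = p["m"] - p["m0"][self.q_cell]
        for name, dev, prior in (
            ("tau", dev_m, TAU_PRIOR),
            ("nu", p["log_sigma"] - np.log(p["sigma0"])[self.q_cell], NU_PRIOR),
        ):
            cur = np.log(p[name])
            prop = cur + steps[name] * rng.standard_normal()

            def target(lv):
                v = np.exp(lv)
                return (
                    -self.Q * lv
                    - 0.5 * np.sum(dev**2) / v**2
                    + float(_log_halfnorm(v, *prior))
                    + lv
                )

            if np.log(rng.random()) < target(prop) - target(cur):
                p[name] = float(np.exp(prop))
                ok = 1.0
            else:
                ok = 0.0
            if adapt is not None:
                steps[name] *= np.exp(adapt * (ok - 0.44))

    def sample(self, config: SamplerConfig) -> dict:
        """Run independent chains; return draws and summaries.

        Output dict has ``draws`` arrays of shape (chains, draws, P) for
        ``m0`` and ``sigma0`` (plus (chains, draws) for tau/nu), per-cell
        summaries (posterior mean, 5th/95th percentiles, split-chain
        R-hat), and a convergence flag (max R-hat < 1.05).
        """
        ch_m0 = np.empty((config.chains, config.draws, self.P))
        ch_s0 = np.empty((config.chains, config.draws, self.P))
        ch_tau = np.empty((config.chains, config.draws))
        ch_nu = np.empty((config.chains, config.draws))
        for ci in range(config.chains):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, ci])
            )
            p = self._init_params(rng)
            steps = {"ls": 0.5, "l0": 0.3, "tau": 0.3, "nu": 0.3,
                     "tm": 0.5, "ts": 0.3}
            for it in range(config.warmup):
                self._sweep(p, steps, rng, adapt=2.0 / np.sqrt(1 + it))
            for it in range(config.draws * config.thin):
                self._sweep(p, steps, rng, adapt=None)
                if it % config.thin == 0:
                    j = it // config.thin
                    ch_m0[ci, j] = p["m0"]
                    ch_s0[ci, j] = p["sigma0"]
                    ch_tau[ci, j] = p["tau"]
                    ch_nu[ci, j] = p["nu"]
        rhat_m0 = _split_rhat(ch_m0)
        rhat_s0 = _split_rhat(ch_s0)
        summary = pd.DataFrame(
            {
                "condition": [c for c, _ in self.cells],
                "x": [x for _, x in self.cells],
                "m0_mean": ch_m0.reshape(-1, self.P).mean(axis=0),
                "m0_q5": np.quantile(ch_m0.reshape(-1, self.P), 0.05, axis=0),
                "m0_q95": np.quantile(ch_m0.reshape(-1, self.P), 0.95, axis=0),
                "sigma0_mean": ch_s0.reshape(-1, self.P).mean(axis=0),
                "sigma0_q5": np.quantile(ch_s0.reshape(-1, self.P), 0.05, axis=0),
                "sigma0_q95": np.quantile(ch_s0.reshape(-1, self.P), 0.95, axis=0),
                "rhat_m0": rhat_m0,
                "rhat_sigma0": rhat_s0,
            }
        )
        max_rhat = float(np.nanmax([rhat_m0.max(), rhat_s0.max()]))
        return {
            "summary": summary,
            "draws": {"m0": ch_m0, "sigma0": ch_s0, "tau": ch_tau, "nu": ch_nu},
            "max_rhat": max_rhat,
            "converged": bool(max_rhat < 1.05),
        }


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor per parameter."""
    c, d = draws.shape[0], draws.shape[1]
    half = d // 2
    segs = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    mean_seg = segs.mean(axis=1)
    var_seg = segs.var(axis=1, ddof=1)
    W = var_seg.mean(axis=0)
    B = half * mean_seg.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_hat / W)
    return np.where(W > 0, out, 1.0)


def log_posterior(params: dict, table: pd.DataFrame) -> float:
    """Joint log posterior density of the hierarchical model (see class)."""
    return HierarchicalModel(table).log_posterior(params)


def sample_posterior(table: pd.DataFrame, config: SamplerConfig | None = None) -> dict:
    """Sample the hierarchical posterior and summarize the fixed effects."""
    model = HierarchicalModel(table)
    res = model.sample(config or SamplerConfig())
    if not res["converged"]:
        import warnings

        warnings.warn(
            f"MCMC convergence diagnostic failed (max R-hat {res['max_rhat']:.3f}); "
            "summaries are still reported",
            RuntimeWarning,
        )
    return res


def simulate_from_model(
    conditions: dict[str, np.ndarray],
    n_subjects: int,
    trials_per_number: int,
    tau: float = 3.0,
    nu: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate responses from the hierarchical model itself.

    Condition-level truth is drawn from the hyperpriors
    (m_0c(x) ~ N(x, 20^2), sigma_0c(x) ~ N+(7, 7^2)); tau and nu are fixed
    at the given plausible values.  Returns (table, truth) where truth has
    one row per (condition, x) cell with the generating m_0c and sigma_0c.
    Used for calibration checks of the sampler.
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for cond, numbers in conditions.items():
        for x in np.asarray(numbers):
            m0 = rng.normal(float(x), M0_PRIOR_SD)
            s0 = 0.0
            while s0 <= 0:
                s0 = rng.normal(*S0_PRIOR)
            truth_rows.append(
                {"condition": cond, "x": int(x), "m0": m0, "sigma0": s0}
            )
            for s in range(n_subjects):
                m_s = rng.normal(m0, tau)
                sig_s = np.exp(rng.normal(np.log(s0), nu))
                resp = rng.normal(m_s, sig_s, size=trials_per_number)
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": s,
                            "condition": cond,
                            "x": int(x),
                            "response": resp,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth_rows)
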