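"""Maximum-likelihood fitting and comparison of the observer models.

Supports the full grid of model structures explored in the analysis: the
width-scaling exponent alpha fixed (0, 1/2, 3/4, 1), shared-free, or
per-subject; baseline imprecision nu shared, per-subject, or absent
(motor-noise-only models); motor noise sigma0 shared, per-subject, and/or
per-condition; linear or logarithmic encoding; and a shared lapse rate for
the choice tasks.  Models are ranked by BIC = k ln N - 2 logL.

Also provides the magnitude-split probit with likelihood-ratio test, the
Kolmogorov-Smirnov matching of rescaled per-subject imprecision across
conditions, and random-effects Bayesian model selection (variational
Dirichlet over model frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, ndtr

from . import observer_model as om
from .specs import ChoiceSpec, EncodingSpec, EstimationNoiseSpec, PriorSpec
from .synthetic_data import DISCRIMINATION_PRIORS, ESTIMATION_PRIORS

__all__ = [
    "FitStructure",
    "FitResult",
    "BMSResult",
    "bic",
    "estimation_nll",
    "fit_estimation",
    "discrimination_nll",
    "fit_discrimination",
    "fit_nu_tilde_per_subject",
    "split_magnitude_probit",
    "ks_match",
    "bms_proportions",
]

# parameter search bounds: alpha in [0, 1.5]; noise scales in (1e-6, 50);
# lapse in [0, 0.5] (a lapse above one half is unidentifiable against a
# sign flip of the decision variable)
ALPHA_BOUNDS = (0.0, 1.5)
NU_BOUNDS = (1e-6, 50.0)
SIGMA0_BOUNDS = (1e-6, 50.0)
ETA_BOUNDS = (0.0, 0.5)


@dataclass(frozen=True)
class FitStructure:
    """Which parameters are fixed, shared, or individual in a model fit."""

    alpha_mode: str = "fixed"  # fixed | shared_free | individual
    alpha_value: float | None = 0.5  # used when alpha_mode == 'fixed'
    nu_mode: str = "shared"  # shared | individual | zero
    sigma0_mode: str = "shared"  # shared | individual | shared_per_condition | individual_per_condition
    encoding_kind: str = "linear"
    lapse: str = "none"  # none | shared

    def __post_init__(self) -> None:
        if self.alpha_mode not in ("fixed", "shared_free", "individual"):
            raise ValueError(f"bad alpha_mode {self.alpha_mode!r}")
        if self.nu_mode not in ("shared", "individual", "zero"):
            raise ValueError(f"bad nu_mode {self.nu_mode!r}")
        if self.sigma0_mode not in (
            "shared",
            "individual",
            "shared_per_condition",
            "individual_per_condition",
        ):
            raise ValueError(f"bad sigma0_mode {self.sigma0_mode!r}")
        if self.lapse not in ("none", "shared"):
            raise ValueError(f"bad lapse {self.lapse!r}")
        if self.nu_mode == "zero" and self.alpha_mode != "fixed":
            raise ValueError("no cognitive noise implies no exponent: fix alpha")
        if self.alpha_mode == "fixed" and self.alpha_value is None:
            raise ValueError("alpha_mode='fixed' requires alpha_value")

    def label(self) -> str:
        a = (
            f"alpha={self.alpha_value}"
            if self.alpha_mode == "fixed"
            else f"alpha_{self.alpha_mode}"
        )
        return f"{a},nu_{self.nu_mode},sigma0_{self.sigma0_mode},{self.encoding_kind},lapse_{self.lapse}"


@dataclass
class FitResult:
    structure: FitStructure
    params: dict
    logL: float
    k: int
    N: int
    bic: float = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bic = bic(self.logL, self.k, self.N)


@dataclass
class BMSResult:
    dirichlet: np.ndarray
    expected_frequencies: np.ndarray
    iterations: int


def bic(logL: float, k: int, N: int) -> float:
    """Bayesian Information Criterion k ln N - 2 logL (lower is better)."""
    if N < 1 or k < 0:
        raise ValueError("need N >= 1 and k >= 0")
    return k * np.log(N) - 2.0 * logL


# --------------------------------------------------------------------------
# estimation task
# --------------------------------------------------------------------------


class _EstimationData:
    """Pre-aggregated (x, response) counts per subject and condition."""

    def __init__(self, table: pd.DataFrame, priors: dict[str, PriorSpec]):
        self.priors = priors
        self.subjects = np.sort(table["subject"].unique())
        self.conditions = [c for c in priors if c in set(table["condition"])]
        self.counts: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.N = len(table)
        for (s, c), g in table.groupby(["subject", "condition"], sort=True):
            prior = priors[c]
            if not (prior.contains(g["x"]).all() and prior.contains(g["response"]).all()):
                raise ValueError(
                    f"subject {s}, condition {c}: x or response outside prior range"
                )
            pairs = (
                g.groupby(["x", "response"]).size().reset_index(name="n")
            )
            self.counts[(s, c)] = (
                pairs["x"].to_numpy() - prior.x_min,
                pairs["response"].to_numpy() - prior.x_min,
                pairs["n"].to_numpy().astype(float),
            )


def _resolve_estimation_params(
    params: dict, structure: FitStructure, subjects, conditions
):
    """Yield (subject, condition) -> (nu, sigma0, alpha) assignments."""
    for si, s in enumerate(subjects):
        if structure.nu_mode == "zero":
            nu = 0.0
        elif structure.nu_mode == "shared":
            nu = float(params["nu"])
        else:
            nu = float(np.asarray(params["nu"])[si])
        if structure.alpha_mode == "fixed":
            alpha = float(structure.alpha_value)
        elif structure.alpha_mode == "shared_free":
            alpha = float(params["alpha"])
        else:
            alpha = float(np.asarray(params["alpha"])[si])
        for ci, c in enumerate(conditions):
            sm = structure.sigma0_mode
            if sm == "shared":
                s0 = float(params["sigma0"])
            elif sm == "individual":
                s0 = float(np.asarray(params["sigma0"])[si])
            elif sm == "shared_per_condition":
                s0 = float(np.asarray(params["sigma0"])[ci])
            else:
                s0 = float(np.asarray(params["sigma0"])[si, ci])
            yield (s, c), (nu, s0, alpha)


def estimation_nll(
    table: pd.DataFrame,
    params: dict,
    structure: FitStructure,
    priors: dict[str, PriorSpec] | None = None,
    _data: _EstimationData | None = None,
) -> float:
    """Negative log likelihood of estimation responses under the observer model."""
    priors = priors or ESTIMATION_PRIORS
    data = _data if _data is not None else _EstimationData(table, priors)
    cache: dict[tuple, np.ndarray] = {}
    nll = 0.0
    for (s, c), (nu, s0, alpha) in _resolve_estimation_params(
        params, structure, data.subjects, data.conditions
    ):
        if (s, c) not in data.counts:
            continue
        key = (round(nu, 12), round(s0, 12), round(alpha, 12), c)
        if key not in cache:
            enc = EncodingSpec(structure.encoding_kind, nu, alpha)
            cache[key] = om.response_pmf_table(
                enc, EstimationNoiseSpec(s0), data.priors[c]
            )
        pmf = cache[key]
        xi, ri, n = data.counts[(s, c)]
        p = pmf[xi, ri]
        nll -= float(n @ np.log(np.maximum(p, 1e-300)))
    return nll


# documented deterministic multi-start grid (nu, sigma0, alpha); structures
# that do not use a coordinate collapse duplicates automatically
_ESTIMATION_STARTS = [
    (0.3, 1.0, 0.5),
    (1.0, 1.0, 0.5),
    (3.0, 1.0, 0.5),
    (0.3, 4.0, 0.5),
    (1.0, 4.0, 0.5),
    (3.0, 4.0, 0.5),
    (1.0, 2.0, 0.1),
    (1.0, 2.0, 0.75),
    (1.0, 2.0, 1.2),
    (0.5, 0.5, 0.5),
]


def _estimation_param_layout(structure: FitStructure, n_subjects: int, n_conditions: int):
    """(name, shape, bounds) blocks of the free-parameter vector."""
    layout = []
    if structure.nu_mode == "shared":
        layout.append(("nu", (), NU_BOUNDS))
    elif structure.nu_mode == "individual":
        layout.append(("nu", (n_subjects,), NU_BOUNDS))
    if structure.alpha_mode == "shared_free":
        layout.append(("alpha", (), ALPHA_BOUNDS))
    elif structure.alpha_mode == "individual":
        layout.append(("alpha", (n_subjects,), ALPHA_BOUNDS))
    sm = structure.sigma0_mode
    shape = {
        "shared": (),
        "individual": (n_subjects,),
        "shared_per_condition": (n_conditions,),
        "individual_per_condition": (n_subjects, n_conditions),
    }[sm]
    layout.append(("sigma0", shape, SIGMA0_BOUNDS))
    return layout


def _pack(layout, params):
    return np.concatenate(
        [np.ravel(np.broadcast_to(params[name], shape or ())) for name, shape, _ in layout]
    )


def _unpack(layout, z):
    params, i = {}, 0
    for name, shape, _ in layout:
        size = int(np.prod(shape)) if shape else 1
        block = z[i : i + size]
        params[name] = float(block[0]) if not shape else block.reshape(shape)
        i += size
    return params


def fit_estimation(
    table: pd.DataFrame,
    structure: FitStructure,
    starts: list[tuple[float, float, float]] | None = None,
    priors: dict[str, PriorSpec] | None = None,
) -> FitResult:
    """Fit the estimation observer model by bounded maximum likelihood.

    Multi-start bounded quasi-Newton (L-BFGS-B) from a documented
    deterministic start grid; returns the best local optimum.  Per-subject
    structures make the vector large; they remain exact joint fits (the
    likelihood is separable across subjects only when every free parameter
    is individual, and L-BFGS-B handles the joint problem directly).
    """
    priors = priors or ESTIMATION_PRIORS
    data = _EstimationData(table, priors)
    starts = starts if starts is not None else _ESTIMATION_STARTS
    layout = _estimation_param_layout(structure, len(data.subjects), len(data.conditions))
    bounds = []
    for name, shape, b in layout:
        bounds.extend([b] * (int(np.prod(shape)) if shape else 1))

    def nll_vec(z):
        return estimation_nll(table, _unpack(layout, z), structure, priors, _data=data)

    start_vecs = []
    for nu0, s00, a0 in starts:
        p0 = {"nu": nu0, "alpha": a0, "sigma0": s00}
        z0 = _pack(layout, {n: p0[n] for n, _, _ in layout})
        if not any(np.allclose(z0, v) for v in start_vecs):
            start_vecs.append(z0)

    best = None
    n_fail = 0
    for z0 in start_vecs:
        res = optimize.minimize(
            nll_vec, z0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {len(start_vecs)} starts failed for {structure.label()}")
    params = _unpack(layout, best.x)
    k = len(best.x)
    return FitResult(
        structure=structure,
        params=params,
        logL=-float(best.fun),
        k=k,
        N=data.N,
        diagnostics={"n_starts": len(start_vecs), "n_failed": n_fail, "nit": int(best.nit)},
    )


# --------------------------------------------------------------------------
# discrimination task
# --------------------------------------------------------------------------


def _choice_prob_vec(d: np.ndarray, scale, eta) -> np.ndarray:
    """(1 - eta) Phi(d / scale) + eta / 2, vectorized over trials."""
    return (1.0 - eta) * ndtr(d / scale) + eta / 2.0


def _discrimination_design(table: pd.DataFrame, structure: FitStructure,
                           priors: dict[str, PriorSpec]):
    if not set(table["choice"]).issubset({"red", "blue"}):
        raise ValueError("choices must be 'red' or 'blue'")
    cond = table["condition"].to_numpy()
    conds = [c for c in priors if c in set(cond)]
    if len(conds) < 2 and structure.alpha_mode != "fixed":
        raise ValueError(
            "single-condition data identifies only nu_tilde = nu w^alpha; "
            "fix alpha (e.g. 0 with nu acting as nu_tilde) or pool conditions"
        )
    w = np.array([priors[c].width for c in cond], dtype=float)
    d = (
        om.mu(table["x_R"].to_numpy(), structure.encoding_kind)
        - om.mu(table["x_B"].to_numpy(), structure.encoding_kind)
    )
    y = (table["choice"].to_numpy() == "red").astype(float)
    return d, w, y


def discrimination_nll(
    table: pd.DataFrame,
    params: dict,
    structure: FitStructure,
    priors: dict[str, PriorSpec] | None = None,
) -> float:
    """Bernoulli NLL of discrimination choices under the probit choice rule."""
    priors = priors or DISCRIMINATION_PRIORS
    d, w, y = _discrimination_design(table, structure, priors)
    alpha = (
        float(structure.alpha_value)
        if structure.alpha_mode == "fixed"
        else float(params["alpha"])
    )
    nu = float(params["nu"])
    eta = float(params.get("eta", 0.0)) if structure.lapse == "shared" else 0.0
    scale = np.sqrt(2.0) * nu * w**alpha
    p = np.clip(_choice_prob_vec(d, scale, eta), 1e-12, 1.0 - 1e-12)
    return float(-(y @ np.log(p) + (1.0 - y) @ np.log1p(-p)))


_DISCRIMINATION_STARTS = [
    (0.05, 0.6, 0.02),
    (0.2, 0.6, 0.02),
    (1.0, 0.6, 0.02),
    (0.2, 0.3, 0.1),
    (0.2, 1.0, 0.1),
    (0.5, 0.75, 0.0),
]


def fit_discrimination(
    table: pd.DataFrame,
    structure: FitStructure,
    starts: list[tuple[float, float, float]] | None = None,
    priors: dict[str, PriorSpec] | None = None,
) -> FitResult:
    """Fit the probit choice model (nu, optionally alpha and eta) by MLE."""
    priors = priors or DISCRIMINATION_PRIORS
    d, w, y = _discrimination_design(table, structure, priors)
    free_alpha = structure.alpha_mode == "shared_free"
    free_eta = structure.lapse == "shared"
    starts = starts if starts is not None else _DISCRIMINATION_STARTS

    def nll_vec(z):
        i = 0
        nu = np.exp(z[i]); i += 1
        alpha = z[i] if free_alpha else float(structure.alpha_value)
        i += free_alpha
        eta = z[i] if free_eta else 0.0
        scale = np.sqrt(2.0) * nu * w**alpha
        p = np.clip(_choice_prob_vec(d, scale, eta), 1e-12, 1.0 - 1e-12)
        return float(-(y @ np.log(p) + (1.0 - y) @ np.log1p(-p)))

    bounds = [tuple(np.log(NU_BOUNDS))]
    if free_alpha:
        bounds.append(ALPHA_BOUNDS)
    if free_eta:
        bounds.append(ETA_BOUNDS)

    best = None
    seen = []
    for nu0, a0, e0 in starts:
        z0 = [np.log(nu0)] + ([a0] if free_alpha else []) + ([e0] if free_eta else [])
        z0 = np.array(z0)
        if any(np.allclose(z0, v) for v in seen):
            continue
        seen.append(z0)
        res = optimize.minimize(nll_vec, z0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    i = 0
    params = {"nu": float(np.exp(best.x[i]))}
    i += 1
    if free_alpha:
        params["alpha"] = float(best.x[i]); i += 1
    else:
        params["alpha"] = float(structure.alpha_value)
    if free_eta:
        params["eta"] = float(best.x[i])
    k = len(best.x)
    return FitResult(
        structure=structure, params=params, logL=-float(best.fun), k=k, N=len(y),
        diagnostics={"n_starts": len(seen), "nit": int(best.nit)},
    )


def fit_nu_tilde_per_subject(
    table: pd.DataFrame,
    eta: float | None = None,
    encoding_kind: str = "linear",
) -> pd.DataFrame:
    """Per-subject fits of the condition-level imprecision nu_tilde.

    A subject who experienced a single condition identifies only
    nu_tilde = nu w^alpha.  Fits (nu_tilde, eta) per subject (or nu_tilde
    alone if ``eta`` is given) and returns a frame with columns
    ``subject, condition, nu_tilde, eta``.
    """
    rows = []
    for s, g in table.groupby("subject", sort=True):
        d = (
            om.mu(g["x_R"].to_numpy(), encoding_kind)
            - om.mu(g["x_B"].to_numpy(), encoding_kind)
        )
        y = (g["choice"].to_numpy() == "red").astype(float)

        def nll(z):
            nt = np.exp(z[0])
            e = eta if eta is not None else z[1]
            p = np.clip(_choice_prob_vec(d, np.sqrt(2.0) * nt, e), 1e-12, 1 - 1e-12)
            return float(-(y @ np.log(p) + (1 - y) @ np.log1p(-p)))

        bounds = [tuple(np.log(NU_BOUNDS))] + ([] if eta is not None else [ETA_BOUNDS])
        best = None
        for nt0 in (0.5, 2.0, 8.0):
            z0 = np.array([np.log(nt0)] + ([] if eta is not None else [0.02]))
            res = optimize.minimize(nll, z0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        rows.append(
            {
                "subject": s,
                "condition": g["condition"].iloc[0],
                "nu_tilde": float(np.exp(best.x[0])),
                "eta": float(eta if eta is not None else best.x[1]),
            }
        )
    return pd.DataFrame(rows)


def split_magnitude_probit(table: pd.DataFrame, threshold: float = 50.0) -> dict:
    """Probit with lapses, allowing the noise scale to differ by magnitude.

    Keeps only trials with both averages strictly on one side of
    ``threshold``; fits a two-scale model (small vs large averages) and the
    one-scale restriction, and reports the likelihood-ratio test
    (chi-square, 1 df).
    """
    both_small = (table["x_R"] < threshold) & (table["x_B"] < threshold)
    both_large = (table["x_R"] > threshold) & (table["x_B"] > threshold)
    sub = table[both_small | both_large]
    small = both_small[both_small | both_large].to_numpy()
    if small.all() or (~small).all():
        raise ValueError("one magnitude stratum is empty")
    d = (sub["x_R"] - sub["x_B"]).to_numpy(dtype=float)
    y = (sub["choice"].to_numpy() == "red").astype(float)

    def nll(z, two_scale: bool):
        if two_scale:
            sc = np.where(small, np.exp(z[0]), np.exp(z[1]))
            eta = z[2]
        else:
            sc = np.exp(z[0])
            eta = z[1]
        p = np.clip(_choice_prob_vec(d, sc, eta), 1e-12, 1 - 1e-12)
        return float(-(y @ np.log(p) + (1 - y) @ np.log1p(-p)))

    log_sc_bounds = (np.log(1e-3), np.log(1e3))

    def best_fit(two_scale: bool):
        bounds = [log_sc_bounds] * (2 if two_scale else 1) + [ETA_BOUNDS]
        best = None
        for sc0 in (1.0, 4.0, 12.0):
            z0 = np.array([np.log(sc0)] * (2 if two_scale else 1) + [0.02])
            res = optimize.minimize(
                lambda z: nll(z, two_scale), z0, method="L-BFGS-B", bounds=bounds
            )
            if best is None or res.fun < best.fun:
                best = res
        return best

    full = best_fit(True)
    restricted = best_fit(False)
    lr = max(0.0, 2.0 * (restricted.fun - full.fun))
    return {
        "scale_small": float(np.exp(full.x[0])),
        "scale_large": float(np.exp(full.x[1])),
        "eta": float(full.x[2]),
        "LR_chi2": lr,
        "df": 1,
        "p": float(stats.chi2.sf(lr, df=1)),
        "logL_full": -float(full.fun),
        "logL_restricted": -float(restricted.fun),
    }


def ks_match(
    nu_tilde_by_condition: dict[str, np.ndarray],
    widths: dict[str, float],
    alpha: float,
) -> dict:
    """Two-sample KS test of equality of nu_tilde / w^alpha across conditions.

    If the exponent alpha is the one shared by the population, the rescaled
    per-subject imprecisions are draws from the same distribution in every
    condition and the test should not reject.
    """
    conds = list(nu_tilde_by_condition)
    if len(conds) != 2:
        raise ValueError("expected exactly two conditions")
    a = np.asarray(nu_tilde_by_condition[conds[0]], dtype=float) / widths[conds[0]] ** alpha
    b = np.asarray(nu_tilde_by_condition[conds[1]], dtype=float) / widths[conds[1]] ** alpha
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(a, b, method="auto")
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def bms_proportions(log_evidences: np.ndarray, tol: float = 1e-6,
                    max_iter: int = 10_000) -> BMSResult:
    """Random-effects Bayesian model selection over per-subject evidences.

    Variational update of a Dirichlet posterior over population model
    frequencies from a uniform Dirichlet(1, ..., 1) prior; with two models
    the posterior is a Beta distribution.  Per-subject log model evidence is
    conventionally approximated by -BIC/2.
    """
    ev = np.asarray(log_evidences, dtype=float)
    if ev.ndim != 2 or ev.shape[1] < 2:
        raise ValueError("need a subjects x models (>= 2) array")
    if not np.all(np.isfinite(ev)):
        raise ValueError("log evidences must be finite")
    n, m = ev.shape
    alpha0 = np.ones(m)
    alpha = alpha0.copy()
    for it in range(1, max_iter + 1):
        logu = ev + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    return BMSResult(
        dirichlet=alpha,
        expected_frequencies=alpha / alpha.sum(),
        iterations=it,
    )
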