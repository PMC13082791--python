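"""Descriptive battery for the estimation and discrimination trial tables.

Binned excursion variances (trial-to-trial variability with the per-number
mean removed), coefficient-of-variation curves, relative errors, the
two-point affine extrapolation of variance across prior widths, binned
psychometric summaries with configurable width-normalization, the standard
tests (Levene, Fisher exact, Holm correction) and first/second-half
stability summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .specs import PriorSpec
from .synthetic_data import DISCRIMINATION_PRIORS, ESTIMATION_PRIORS

__all__ = [
    "BinScheme",
    "default_bins",
    "excursion_variance",
    "cv_curve",
    "relative_error",
    "affine_extrapolate",
    "psychometric_bins",
    "psychometric_collapse_gap",
    "levene",
    "fisher_exact_2x2",
    "holm_adjust",
    "half_split",
]


@dataclass(frozen=True)
class BinScheme:
    """Five integer ranges partitioning a condition's prior support."""

    condition: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.ranges) != 5:
            raise ValueError("expected five bins")

    def assign(self, x) -> np.ndarray:
        """Bin index (0-4) for each value; -1 if outside every bin."""
        x = np.asarray(x)
        out = np.full(x.shape, -1)
        for i, (lo, hi) in enumerate(self.ranges):
            out[(x >= lo) & (x <= hi)] = i
        return out


# The middle bin is centered on the prior midpoint; the second and fourth
# bins match its size; the first and last take the remaining integers.
_DEFAULT_BINS = {
    "Narrow": ((50, 52), (53, 57), (58, 62), (63, 67), (68, 70)),
    "Medium": ((40, 46), (47, 55), (56, 64), (65, 73), (74, 80)),
    "Wide": ((30, 40), (41, 53), (54, 66), (67, 79), (80, 90)),
}


def default_bins(condition: str) -> BinScheme:
    """The five-bin scheme of the given estimation condition."""
    if condition not in _DEFAULT_BINS:
        raise ValueError(f"unknown condition {condition!r}")
    return BinScheme(condition, _DEFAULT_BINS[condition])


def excursion_variance(
    table: pd.DataFrame, bins: BinScheme, ddof: int = 1
) -> pd.DataFrame:
    """Per-bin variance of response excursions from the per-number mean.

    Subtracting the mean response to each presented number isolates
    trial-to-trial variability from the heterogeneity of numbers within a
    bin.  Numbers with a single trial contribute a zero excursion; they are
    counted in ``n_single``.  Empty bins yield NaN, not zero.
    """
    t = table.copy()
    t["excursion"] = t["response"] - t.groupby("x")["response"].transform("mean")
    t["bin"] = bins.assign(t["x"])
    per_x_count = t.groupby("x")["response"].transform("size")
    rows = []
    for i in range(5):
        g = t[t["bin"] == i]
        if len(g) < 2:
            var = np.nan
        else:
            var = float(g["excursion"].var(ddof=ddof))
        rows.append(
            {
                "bin": i,
                "range": bins.ranges[i],
                "variance": var,
                "n": len(g),
                "n_single": int((per_x_count[t["bin"] == i] == 1).sum()),
            }
        )
    return pd.DataFrame(rows)


def cv_curve(table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Coefficient of variation sd(response)/mean(response) per presented number.

    A constant CV across numbers is the signature of scalar variability;
    the observer model instead predicts a CV that falls with the number.
    """
    g = table.groupby("x")["response"]
    out = pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=ddof), "n": g.size()}
    ).reset_index()
    out = out[out["n"] >= 2].copy()
    if (out["mean"] == 0).any():
        raise ValueError("mean response of zero; CV undefined")
    out["cv"] = out["sd"] / out["mean"]
    return out


def relative_error(table: pd.DataFrame, w: float) -> dict:
    """Mean absolute error |response - x| and its ratio to the prior width."""
    if len(table) == 0:
        raise ValueError("empty table")
    mae = float(np.abs(table["response"] - table["x"]).mean())
    return {"mean_abs_error": mae, "ratio": mae / w}


def affine_extrapolate(
    points: list[tuple[float, float]], transform: str, target_w: float
) -> float:
    """Two-point affine extrapolation of response variance across widths.

    Solves variance = c0 + c1 * T(w) through the two given (w, variance)
    points, with T(w) = w (affine in the width, the scaling the data
    support) or T(w) = w^2 (the range-normalization prediction), and
    evaluates at ``target_w``.
    """
    if len(points) != 2:
        raise ValueError("exactly two (w, variance) points required")
    tf = {"width": lambda w: w, "width_squared": lambda w: w**2}
    if transform not in tf:
        raise ValueError(f"unknown transform {transform!r}")
    (w1, v1), (w2, v2) = points
    t1, t2 = tf[transform](w1), tf[transform](w2)
    if t1 == t2:
        raise ValueError("coincident abscissae")
    slope = (v2 - v1) / (t2 - t1)
    return float(v1 + slope * (tf[transform](target_w) - t1))


def _binomial_ci(k: np.ndarray, n: np.ndarray, method: str = "normal"):
    p = k / n
    if method == "normal":
        half = 1.959963984540054 * np.sqrt(np.maximum(p * (1 - p), 0.25 / n) / n)
        return np.clip(p - half, 0, 1), np.clip(p + half, 0, 1)
    if method == "exact":
        lo = stats.beta.ppf(0.025, k, n - k + 1)
        hi = stats.beta.ppf(0.975, k + 1, n - k)
        return np.where(k == 0, 0.0, lo), np.where(k == n, 1.0, hi)
    raise ValueError(f"unknown CI method {method!r}")


def psychometric_bins(
    table: pd.DataFrame,
    normalizer_alpha: float = 0.75,
    n_bins: int = 8,
    priors: dict[str, PriorSpec] | None = None,
    ci_method: str = "normal",
) -> dict[str, pd.DataFrame]:
    """Binned psychometric summaries of a discrimination table.

    ``signed``: P('red') against x_R - x_B.  ``correct``: P(correct)
    against |x_R - x_B| / w^alpha, the width-normalized difference under
    which the curves of all conditions should collapse when alpha matches
    the population's scaling exponent.  Bin edges are equal-count quantiles
    over the pooled data; binomial 95% CIs use the normal approximation by
    default (Clopper-Pearson with ``ci_method='exact'``).
    """
    priors = priors or DISCRIMINATION_PRIORS
    d = (table["x_R"] - table["x_B"]).to_numpy(dtype=float)
    w = np.array([priors[c].width for c in table["condition"]], dtype=float)
    red = (table["choice"].to_numpy() == "red").astype(float)
    correct = np.where(d > 0, red, np.where(d < 0, 1 - red, np.nan))
    out = {}
    for key, xval, yval in (
        ("signed", d, red),
        ("correct", np.abs(d) / w**normalizer_alpha, correct),
    ):
        keep = ~np.isnan(yval)
        xv, yv, cv = xval[keep], yval[keep], table["condition"].to_numpy()[keep]
        edges = np.unique(np.quantile(xv, np.linspace(0, 1, n_bins + 1)))
        rows = []
        for cond in dict.fromkeys(table["condition"]):
            m = cv == cond
            idx = np.clip(np.searchsorted(edges, xv[m], side="right") - 1, 0, len(edges) - 2)
            for b in range(len(edges) - 1):
                sel = idx == b
                n = int(sel.sum())
                if n == 0:
                    rows.append(
                        {"condition": cond, "bin": b, "x": np.nan, "p": np.nan,
                         "n": 0, "ci_lo": np.nan, "ci_hi": np.nan}
                    )
                    continue
                k = float(yv[m][sel].sum())
                lo, hi = _binomial_ci(np.array([k]), np.array([n]), ci_method)
                rows.append(
                    {"condition": cond, "bin": b, "x": float(xv[m][sel].mean()),
                     "p": k / n, "n": n, "ci_lo": float(lo[0]), "ci_hi": float(hi[0])}
                )
        out[key] = pd.DataFrame(rows)
    return out


def psychometric_collapse_gap(
    table: pd.DataFrame,
    normalizer_alpha: float,
    n_bins: int = 8,
    priors: dict[str, PriorSpec] | None = None,
) -> float:
    """Maximum binwise gap in P(correct) between conditions after rescaling.

    Smallest when ``normalizer_alpha`` equals the exponent with which the
    population's imprecision actually scales.
    """
    frame = psychometric_bins(table, normalizer_alpha, n_bins, priors)["correct"]
    pivot = frame.pivot_table(index="bin", columns="condition", values="p")
    gaps = (pivot.max(axis=1) - pivot.min(axis=1)).dropna()
    return float(gaps.max())


def levene(groups: list[np.ndarray], center: str = "mean") -> dict:
    """Levene's test of equality of variances (mean-centered by default).

    ``center='median'`` gives the Brown-Forsythe variant.
    """
    if len(groups) < 2 or any(len(np.asarray(g)) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    W, p = stats.levene(*groups, center=center)
    return {"W": float(W), "p": float(p)}


def fisher_exact_2x2(counts) -> dict:
    """Two-sided Fisher exact test on a 2x2 contingency table."""
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    return {"OR": float(odds), "p": float(p)}


def holm_adjust(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def half_split(
    table: pd.DataFrame,
    kind: str = "estimation",
    priors: dict[str, PriorSpec] | None = None,
    normalizer_alpha: float = 0.75,
) -> dict:
    """First/second-half stability summaries and matching tests.

    Estimation tables: per-condition, per-bin excursion variances in each
    half with Levene tests and Holm-adjusted p-values.  Discrimination
    tables: per-half psychometric summaries and Fisher exact tests of the
    per-bin choice proportions, Holm-adjusted.
    """
    if "half" not in table.columns:
        raise ValueError("table has no 'half' column")
    halves = {h: table[table["half"] == h] for h in ("first", "second")}
    if kind == "estimation":
        priors = priors or ESTIMATION_PRIORS
        rows, pvals = [], []
        for cond in dict.fromkeys(table["condition"]):
            bins = default_bins(cond)
            per_half = {}
            for h, sub in halves.items():
                sc = sub[sub["condition"] == cond].copy()
                sc["excursion"] = sc["response"] - sc.groupby("x")["response"].transform("mean")
                sc["bin"] = bins.assign(sc["x"])
                per_half[h] = sc
            for b in range(5):
                g1 = per_half["first"].loc[per_half["first"]["bin"] == b, "excursion"]
                g2 = per_half["second"].loc[per_half["second"]["bin"] == b, "excursion"]
                if len(g1) < 2 or len(g2) < 2:
                    continue
                res = levene([g1.to_numpy(), g2.to_numpy()])
                rows.append(
                    {"condition": cond, "bin": b,
                     "var_first": float(g1.var(ddof=1)),
                     "var_second": float(g2.var(ddof=1)), "p": res["p"]}
                )
                pvals.append(res["p"])
        frame = pd.DataFrame(rows)
        frame["p_holm"] = holm_adjust(pvals) if pvals else np.nan
        return {"tests": frame}
    if kind == "discrimination":
        priors = priors or DISCRIMINATION_PRIORS
        summaries = {
            h: psychometric_bins(sub, normalizer_alpha, priors=priors)
            for h, sub in halves.items()
        }
        rows, pvals = [], []
        f1 = summaries["first"]["signed"]
        f2 = summaries["second"]["signed"]
        merged = f1.merge(f2, on=["condition", "bin"], suffixes=("_1", "_2"))
        for _, r in merged.iterrows():
            if r["n_1"] == 0 or r["n_2"] == 0:
                continue
            k1, k2 = round(r["p_1"] * r["n_1"]), round(r["p_2"] * r["n_2"])
            res = fisher_exact_2x2(
                [[k1, r["n_1"] - k1], [k2, r["n_2"] - k2]]
            )
            rows.append({"condition": r["condition"], "bin": r["bin"], "p": res["p"]})
            pvals.append(res["p"])
        frame = pd.DataFrame(rows)
        frame["p_holm"] = holm_adjust(pvals) if pvals else np.nan
        return {"tests": frame, "summaries": summaries}
    raise ValueError(f"unknown kind {kind!r}")
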