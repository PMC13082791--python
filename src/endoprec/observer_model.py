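"""Gaussian encoding / Bayesian-mean decoding observer for numerosity tasks.

The observer receives an internal representation r | x ~ N(mu(x), nu^2 w^(2 alpha))
of a presented number x, where mu is the identity (linear encoding) or the
natural logarithm (logarithmic encoding), w is the width of the uniform prior
from which stimuli are drawn, nu a baseline imprecision and alpha the exponent
governing how the imprecision scales with the prior width.  In the estimation
task the observer reports the posterior mean x*(r) = E[x | r] corrupted by
truncated, rounded motor noise; in the discrimination (and risky-choice)
tasks it compares two independently encoded magnitudes, which yields a probit
choice rule with an optional lapse mixture.

All likelihood computations are deterministic (fixed quadrature) so they can
be used inside maximum-likelihood optimizers.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp, ndtr

from .specs import ChoiceSpec, EncodingSpec, EstimationNoiseSpec, PriorSpec

__all__ = [
    "mu",
    "mu_prime",
    "fisher_information",
    "posterior_mean",
    "response_pmf",
    "response_pmf_table",
    "choice_probability",
    "range_normalized_response",
    "model_sd_curve",
]

# Fixed quadrature over the internal representation r: nodes span
# mu(x) +/- QUAD_SPAN representation sds.  Deterministic likelihoods matter
# more than the last decimal of quadrature accuracy here.
QUAD_NODES = 201
QUAD_SPAN = 6.0


def mu(x, kind: str):
    """Encoding function: identity (linear) or natural log (logarithmic)."""
    x = np.asarray(x, dtype=float)
    if kind == "linear":
        return x
    if kind == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic encoding requires x > 0")
        return np.log(x)
    raise ValueError(f"unknown encoding kind {kind!r}")


def mu_prime(x, kind: str):
    x = np.asarray(x, dtype=float)
    if kind == "linear":
        return np.ones_like(x)
    if kind == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic encoding requires x > 0")
        return 1.0 / x
    raise ValueError(f"unknown encoding kind {kind!r}")


def fisher_information(x, enc: EncodingSpec, w: float):
    """Fisher information I(x) = (mu'(x) / (nu w^alpha))^2 of the encoding."""
    if w <= 0:
        raise ValueError("w must be > 0")
    if enc.nu == 0:
        raise ValueError("Fisher information undefined for nu = 0")
    return (mu_prime(x, enc.kind) / enc.rep_sd(w)) ** 2


def posterior_mean(r, enc: EncodingSpec, prior: PriorSpec):
    """Bayesian posterior mean x*(r) = E[x | r] under the discrete uniform prior.

    Computed in log space over the integer support; strictly increasing in r
    and bounded in [x_min, x_max].  In the noiseless limit (nu = 0) the
    posterior is degenerate and the encoding is inverted directly.
    """
    r = np.asarray(r, dtype=float)
    sd = enc.rep_sd(prior.width)
    support = prior.support().astype(float)
    if sd == 0.0:
        if enc.kind == "linear":
            x = r
        else:
            x = np.exp(r)
        return np.clip(x, prior.x_min, prior.x_max)
    mu_k = mu(support, enc.kind)
    # log weights: log pi(k) + log phi(r; mu(k), sd^2); uniform prior cancels
    z = -0.5 * ((r[..., None] - mu_k) / sd) ** 2
    log_norm = logsumexp(z, axis=-1)
    wts = np.exp(z - log_norm[..., None])
    return wts @ support


def _motor_cell_masses(centers: np.ndarray, sigma0: float, prior: PriorSpec) -> np.ndarray:
    """Probability mass of each integer response cell under truncated motor noise.

    The motor stage draws from N(center, sigma0^2) truncated to
    [x_min, x_max]; the draw is rounded to the nearest integer, with the
    boundary cells [x_min, x_min + 1/2] and [x_max - 1/2, x_max] absorbing
    everything beyond the half-integer edges.  Returns an array of shape
    centers.shape + (n_support,) that sums to 1 along the last axis.
    """
    support = prior.support().astype(float)
    lo = np.maximum(support - 0.5, prior.x_min)
    hi = np.minimum(support + 0.5, prior.x_max)
    centers = np.asarray(centers, dtype=float)
    if sigma0 == 0.0:
        # point-mass motor stage at the rounded center
        idx = np.clip(np.rint(centers).astype(int) - prior.x_min, 0, len(support) - 1)
        out = np.zeros(centers.shape + (len(support),))
        np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
        return out
    c = centers[..., None]
    upper = ndtr((hi - c) / sigma0)
    lower = ndtr((lo - c) / sigma0)
    z = ndtr((prior.x_max - c) / sigma0) - ndtr((prior.x_min - c) / sigma0)
    # centers are posterior means, hence interior: z is bounded away from 0
    return (upper - lower) / z


def response_pmf_table(
    enc: EncodingSpec,
    noise: EstimationNoiseSpec,
    prior: PriorSpec,
    n_nodes: int = QUAD_NODES,
    span: float = QUAD_SPAN,
) -> np.ndarray:
    """P(response | x) for every x in the prior support, as an (nx, nx) matrix.

    Row i is the response pmf for presented number ``support[i]``; each row
    sums to 1 (the quadrature weights are normalized and the motor cells
    partition the truncated range exactly).
    """
    support = prior.support().astype(float)
    sd = enc.rep_sd(prior.width)
    if sd == 0.0:
        # degenerate encoding: the Bayesian estimate equals x itself
        return _motor_cell_masses(support, noise.sigma0, prior)
    t = np.linspace(-span, span, n_nodes)
    q = np.exp(-0.5 * t**2)
    q /= q.sum()
    mu_x = mu(support, enc.kind)
    r = mu_x[:, None] + sd * t[None, :]  # (nx, nj)
    mu_k = mu(support, enc.kind)
    z = -0.5 * ((r[..., None] - mu_k) / sd) ** 2  # (nx, nj, nk)
    z -= z.max(axis=-1, keepdims=True)
    wts = np.exp(z)
    wts /= wts.sum(axis=-1, keepdims=True)
    xstar = wts @ support  # (nx, nj)
    masses = _motor_cell_masses(xstar, noise.sigma0, prior)  # (nx, nj, nk)
    return np.einsum("j,xjk->xk", q, masses)


def response_pmf(
    x: int,
    enc: EncodingSpec,
    noise: EstimationNoiseSpec,
    prior: PriorSpec,
    n_nodes: int = QUAD_NODES,
    span: float = QUAD_SPAN,
) -> tuple[np.ndarray, np.ndarray]:
    """Response pmf for one presented number, as a (support, mass) pair."""
    if not prior.contains(x):
        raise ValueError(f"x={x} outside prior [{prior.x_min}, {prior.x_max}]")
    table = response_pmf_table(enc, noise, prior, n_nodes=n_nodes, span=span)
    return prior.support(), table[int(x) - prior.x_min]


def choice_probability(x_B, x_R, enc: EncodingSpec, w: float, spec: ChoiceSpec):
    """Probability of choosing 'red' given the two averages x_B and x_R.

    P('red') = (1 - eta) * Phi((mu(x_R) - mu(x_B) - bias) / (sqrt(2) nu w^alpha))
               + eta / 2.
    With nu = 0 the probit degenerates to a step function (ties -> 1/2).
    """
    d = mu(x_R, enc.kind) - mu(x_B, enc.kind) - spec.bias
    sd = enc.rep_sd(w)
    if sd == 0.0:
        base = np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))
    else:
        base = ndtr(d / (np.sqrt(2.0) * sd))
    return (1.0 - spec.eta) * base + spec.eta / 2.0


def range_normalized_response(
    x,
    prior: PriorSpec,
    readout_nu: float,
    sigma0: float,
    rng: np.random.Generator,
):
    """Sample integer estimates from the range-normalization baseline model.

    The number is mapped onto the unit range, read out with noise
    eps ~ N(0, readout_nu^2), and mapped back: xhat_pre = x + eps * w.  Motor
    noise of sd sigma0 is then added, the draw truncated to the prior range
    and rounded to the nearest integer.  Before truncation the response
    variance is sigma0^2 + readout_nu^2 w^2, i.e. affine in the squared
    width -- the signature this baseline is designed to exhibit.
    """
    x = np.asarray(x, dtype=float)
    w = prior.width
    pre = x + readout_nu * w * rng.standard_normal(x.shape)
    if sigma0 > 0:
        # truncated-normal motor stage by rejection-free inverse-cdf sampling
        a = ndtr((prior.x_min - pre) / sigma0)
        b = ndtr((prior.x_max - pre) / sigma0)
        u = np.clip(rng.uniform(a, b), 1e-15, 1.0 - 1e-15)
        from scipy.special import ndtri

        pre = pre + sigma0 * ndtri(u)
    pre = np.clip(pre, prior.x_min, prior.x_max)
    return np.rint(pre).astype(int)


def model_sd_curve(
    enc: EncodingSpec, noise: EstimationNoiseSpec, prior: PriorSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied sd of the integer response as a function of x."""
    support = prior.support().astype(float)
    table = response_pmf_table(enc, noise, prior)
    mean = table @ support
    second = table @ support**2
    var = np.maximum(second - mean**2, 0.0)
    return prior.support(), np.sqrt(var)
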