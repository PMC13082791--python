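"""Simulated trial tables for the estimation, discrimination and risky tasks.

The generators reproduce the statistical structure of the experimental
designs: numerosity estimation with three uniform integer priors
([50, 70], [40, 80], [30, 90]; 120 scored trials per condition, 36
subjects), average discrimination with five red and five blue numbers drawn
from a [35, 65] (31 subjects) or [10, 90] (32 subjects) prior and 200 scored
trials, and certain-vs-lottery risky choices with narrow and wide amount
priors.  Responses are generated from the observer model itself
(`endoprec.observer_model`), so every downstream analysis stage can be
exercised and validated without any external data.

Per-subject noise parameters are drawn log-normally around configurable
medians; the width-scaling exponent is shared across subjects.  All
generators are deterministic given the population seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import observer_model as om
from .specs import (
    ChoiceSpec,
    EncodingSpec,
    EstimationNoiseSpec,
    PriorSpec,
    SubjectPopulation,
)

__all__ = [
    "ESTIMATION_PRIORS",
    "DISCRIMINATION_PRIORS",
    "RISKY_PRIORS",
    "gen_estimation",
    "gen_discrimination",
    "gen_risky",
    "reward_estimation",
    "ESTIMATION_COLUMNS",
    "DISCRIMINATION_COLUMNS",
    "RISKY_COLUMNS",
]

# Condition label -> prior, as used in the experiments
ESTIMATION_PRIORS: dict[str, PriorSpec] = {
    "Narrow": PriorSpec(50, 70),
    "Medium": PriorSpec(40, 80),
    "Wide": PriorSpec(30, 90),
}
DISCRIMINATION_PRIORS: dict[str, PriorSpec] = {
    "Narrow": PriorSpec(35, 65),
    "Wide": PriorSpec(10, 90),
}
# Lottery-amount priors for the risky-choice design (synthetic stand-in for
# a narrow/wide manipulation of the amounts offered); the certain amount is
# drawn from the same prior scaled by the lottery probability p = 1/2 so the
# two options are comparable.
RISKY_PRIORS: dict[str, PriorSpec] = {
    "Narrow": PriorSpec(8, 16),
    "Wide": PriorSpec(2, 22),
}

ESTIMATION_COLUMNS = ["subject", "condition", "x", "response", "half"]
DISCRIMINATION_COLUMNS = (
    ["subject", "condition"]
    + [f"r{i}" for i in range(1, 6)]
    + [f"b{i}" for i in range(1, 6)]
    + ["x_R", "x_B", "choice", "half"]
)
RISKY_COLUMNS = ["subject", "condition", "C", "X", "p", "choice"]


def _half_labels(n: int) -> np.ndarray:
    """First/second-half label by trial index (trial < n/2 -> 'first')."""
    return np.where(np.arange(n) < n // 2 + n % 2, "first", "second")


def gen_estimation(
    pop: SubjectPopulation,
    priors: dict[str, PriorSpec] | None = None,
    trials_per_condition: int = 120,
) -> pd.DataFrame:
    """Simulate the estimation task for every subject and condition.

    Presented numbers are uniform over the prior integers; responses are
    sampled from the observer model's response pmf with each subject's
    (nu_s, sigma0_s) and the shared exponent.  Returns a tidy table with
    columns ``subject, condition, x, response, half``.
    """
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    priors = priors or ESTIMATION_PRIORS
    rng = np.random.default_rng(pop.seed)
    nu_s, s0_s = pop.draw_subject_params(rng)
    rows = []
    for s in range(pop.n_subjects):
        for cond, prior in priors.items():
            enc = EncodingSpec(pop.encoding_kind, float(nu_s[s]), pop.shared_alpha)
            noise = EstimationNoiseSpec(float(s0_s[s]))
            table = om.response_pmf_table(enc, noise, prior)
            support = prior.support()
            x = rng.integers(prior.x_min, prior.x_max + 1, size=trials_per_condition)
            u = rng.random(trials_per_condition)
            cdf = np.cumsum(table, axis=1)
            resp = support[
                np.argmax(u[:, None] <= cdf[x - prior.x_min], axis=1)
            ]
            rows.append(
                pd.DataFrame(
                    {
                        "subject": s,
                        "condition": cond,
                        "x": x,
                        "response": resp,
                        "half": _half_labels(trials_per_condition),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def gen_discrimination(
    pop_narrow: SubjectPopulation,
    pop_wide: SubjectPopulation,
    priors: dict[str, PriorSpec] | None = None,
    trials: int = 200,
) -> pd.DataFrame:
    """Simulate the discrimination task (each subject sees one condition).

    Ten numbers per trial are uniform over the prior integers; the choice is
    Bernoulli with the observer model's probit choice probability at the
    trial's two averages.  In the noiseless, lapse-free limit the larger
    average is chosen deterministically (exact ties go to 'red').
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    priors = priors or DISCRIMINATION_PRIORS
    conds = list(priors.keys())
    pops = {conds[0]: pop_narrow, conds[1]: pop_wide}
    rows = []
    subject_offset = 0
    for cond in conds:
        pop, prior = pops[cond], priors[cond]
        rng = np.random.default_rng(pop.seed)
        nu_s, _ = pop.draw_subject_params(rng)
        for s in range(pop.n_subjects):
            enc = EncodingSpec(pop.encoding_kind, float(nu_s[s]), pop.shared_alpha)
            spec = ChoiceSpec(eta=pop.lapse_eta)
            nums = rng.integers(prior.x_min, prior.x_max + 1, size=(trials, 10))
            red, blue = nums[:, :5], nums[:, 5:]
            x_r = red.mean(axis=1)
            x_b = blue.mean(axis=1)
            p_red = np.asarray(om.choice_probability(x_b, x_r, enc, prior.width, spec))
            if enc.nu == 0 and spec.eta == 0:
                p_red = np.where(x_r == x_b, 1.0, p_red)  # tie-break: red
            choice = np.where(rng.random(trials) < p_red, "red", "blue")
            df = pd.DataFrame(
                {
                    "subject": subject_offset + s,
                    "condition": cond,
                    **{f"r{i + 1}": red[:, i] for i in range(5)},
                    **{f"b{i + 1}": blue[:, i] for i in range(5)},
                    "x_R": x_r,
                    "x_B": x_b,
                    "choice": choice,
                    "half": _half_labels(trials),
                }
            )
            rows.append(df)
        subject_offset += pop.n_subjects
    return pd.concat(rows, ignore_index=True)[DISCRIMINATION_COLUMNS]


def gen_risky(
    pop: SubjectPopulation,
    priors: dict[str, PriorSpec] | None = None,
    trials: int = 200,
    bias: float = 0.0,
    p: float = 0.5,
) -> pd.DataFrame:
    """Simulate certain-amount vs. lottery choices (every subject, both conditions).

    The lottery pays X with probability p = 1/2 (zero otherwise); the
    certain amount C is drawn uniformly from the prior scaled by p.  The
    probability of choosing the lottery is the probit rule applied to the
    lottery's expected value against the (bias-adjusted) certain amount,
    with lapses.
    """
    priors = priors or RISKY_PRIORS
    rng = np.random.default_rng(pop.seed)
    nu_s, _ = pop.draw_subject_params(rng)
    rows = []
    for s in range(pop.n_subjects):
        for cond, prior in priors.items():
            enc = EncodingSpec(pop.encoding_kind, float(nu_s[s]), pop.shared_alpha)
            spec = ChoiceSpec(eta=pop.lapse_eta, bias=bias)
            X = rng.uniform(prior.x_min, prior.x_max, size=trials)
            C = rng.uniform(p * prior.x_min, p * prior.x_max, size=trials)
            # decision variable: p X - C - bias, scaled by sqrt(2) nu w^alpha
            p_lot = np.asarray(
                om.choice_probability(C, p * X, enc, prior.width, spec)
            )
            choice = np.where(rng.random(trials) < p_lot, "lottery", "certain")
            rows.append(
                pd.DataFrame(
                    {
                        "subject": s,
                        "condition": cond,
                        "C": C,
                        "X": X,
                        "p": p,
                        "choice": choice,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def reward_estimation(x: int, response: int) -> float:
    """Per-trial reward 0.10 - (response - x)^2 / 600 (USD)."""
    return 0.10 - (response - x) ** 2 / 600.0
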