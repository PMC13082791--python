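"""Shared parameter containers for the observer model and the task designs.

Every container is a small frozen dataclass that validates its fields on
construction and round-trips through plain dicts (and therefore JSON/YAML).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorSpec",
    "EncodingSpec",
    "EstimationNoiseSpec",
    "ChoiceSpec",
    "SubjectPopulation",
]


@dataclass(frozen=True)
class PriorSpec:
    """Uniform integer prior over ``[x_min, x_max]``.

    The prior's width ``w = x_max - x_min`` is the experiment's manipulated
    context variable: all scaling laws in this package are stated in terms
    of it.
    """

    x_min: int
    x_max: int

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError(f"require x_min < x_max, got [{self.x_min}, {self.x_max}]")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def midpoint(self) -> float:
        return (self.x_min + self.x_max) / 2.0

    def support(self) -> np.ndarray:
        """Integer support of the prior, inclusive of both bounds."""
        return np.arange(self.x_min, self.x_max + 1)

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x)
        return (x >= self.x_min) & (x <= self.x_max)

    def to_dict(self) -> dict:
        return {"x_min": self.x_min, "x_max": self.x_max}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(int(d["x_min"]), int(d["x_max"]))


@dataclass(frozen=True)
class EncodingSpec:
    """Gaussian encoding r | x ~ N(mu(x), nu^2 w^(2 alpha)).

    ``kind`` selects the encoding function mu: the identity (linear) or the
    natural logarithm (logarithmic).  ``nu`` is the baseline imprecision and
    ``alpha`` the exponent with which the representation noise scales with
    the prior width.  ``nu = 0`` is allowed only for the explicit
    no-cognitive-noise model variant.
    """

    kind: str = "linear"
    nu: float = 1.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "logarithmic"):
            raise ValueError(f"unknown encoding kind {self.kind!r}")
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def rep_sd(self, w: float) -> float:
        """Standard deviation nu * w**alpha of the internal representation."""
        return self.nu * float(w) ** self.alpha

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingSpec":
        return cls(str(d["kind"]), float(d["nu"]), float(d["alpha"]))


@dataclass(frozen=True)
class EstimationNoiseSpec:
    """Motor (response) noise of the estimation task.

    The response is drawn from a Gaussian centered on the Bayesian estimate
    with sd ``sigma0``, truncated to the prior range (the slider cannot leave
    it) and rounded to the nearest integer.
    """

    sigma0: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be >= 0")

    def to_dict(self) -> dict:
        return {"sigma0": self.sigma0}

    @classmethod
    def from_dict(cls, d: dict) -> "EstimationNoiseSpec":
        return cls(float(d["sigma0"]))


@dataclass(frozen=True)
class ChoiceSpec:
    """Lapse and bias parameters of the binary-choice tasks.

    On a lapse trial (probability ``eta``) either option is chosen with
    probability 1/2.  ``bias`` is subtracted from the decision variable
    before scaling; it is 0 in the symmetric discrimination task and free
    in the risky-choice variant.
    """

    eta: float = 0.0
    bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")

    def to_dict(self) -> dict:
        return {"eta": self.eta, "bias": self.bias}

    @classmethod
    def from_dict(cls, d: dict) -> "ChoiceSpec":
        return cls(float(d["eta"]), float(d.get("bias", 0.0)))


@dataclass(frozen=True)
class SubjectPopulation:
    """Population law for per-subject observer parameters.

    Per-subject baseline imprecision nu_s and motor sd sigma0_s are drawn
    log-normally around configurable medians (noise parameters are positive
    and right-skewed); the width-scaling exponent alpha is shared by all
    subjects, reflecting its task-level (not idiosyncratic) origin.
    """

    n_subjects: int = 36
    nu_median: float = 1.0
    nu_log_sd: float = 0.3
    sigma0_median: float = 2.0
    sigma0_log_sd: float = 0.3
    shared_alpha: float = 0.5
    encoding_kind: str = "linear"
    lapse_eta: float = 0.0
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.nu_log_sd < 0 or self.sigma0_log_sd < 0:
            raise ValueError("dispersions must be >= 0")
        if not 0.0 <= self.lapse_eta <= 1.0:
            raise ValueError("lapse_eta must be in [0, 1]")
        if self.encoding_kind not in ("linear", "logarithmic"):
            raise ValueError(f"unknown encoding kind {self.encoding_kind!r}")
        if self.shared_alpha < 0:
            raise ValueError("shared_alpha must be >= 0")

    def draw_subject_params(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw (nu_s, sigma0_s) arrays of length ``n_subjects``."""
        nu = self.nu_median * np.exp(self.nu_log_sd * rng.standard_normal(self.n_subjects))
        s0 = self.sigma0_median * np.exp(
            self.sigma0_log_sd * rng.standard_normal(self.n_subjects)
        )
        return nu, s0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectPopulation":
        return cls(**d)


def to_json(spec) -> str:
    """Serialize any spec in this module to a JSON string."""
    return json.dumps(spec.to_dict())
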