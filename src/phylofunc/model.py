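"""Model parameters, priors, and elementary transition/error probabilities.

The evolutionary model is a two-state (function absent/present) Markov
process running root-to-leaves over a gene tree.  Each branch applies a
gain probability mu01 and a loss probability mu10 chosen by the event
class of the *parent* node (duplication vs speciation); the root state is
Bernoulli(pi).  Observed leaf annotations pass through an error layer
with mislabeling probabilities psi01 (false presence) and psi10 (false
absence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import yaml
from scipy.special import betaln

from .treeio import DUPLICATION, SPECIATION

#: Canonical parameter order used everywhere arrays are exchanged.
PARAM_NAMES: Tuple[str, ...] = (
    "pi", "mu01_d", "mu10_d", "mu01_s", "mu10_s", "psi01", "psi10",
)


@dataclass(frozen=True)
class ModelParameters:
    """The seven probabilities of the gene-function evolution model.

    pi      -- probability the root node has the function
    mu01_d  -- gain probability on a branch following a duplication
    mu10_d  -- loss probability on a branch following a duplication
    mu01_s  -- gain probability on a branch following a speciation
    mu10_s  -- loss probability on a branch following a speciation
    psi01   -- probability an absent function is annotated present
    psi10   -- probability a present function is annotated absent

    Values of exactly 0 or 1 are legal; downstream code guards log(0).
    """

    pi: float
    mu01_d: float
    mu10_d: float
    mu01_s: float
    mu10_s: float
    psi01: float
    psi10: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def baseline(cls, pi: float, mu01: float, mu10: float,
                 psi01: float, psi10: float) -> "ModelParameters":
        """The 5-parameter model: gain/loss shared across event classes."""
        return cls(pi, mu01, mu10, mu01, mu10, psi01, psi10)

    @property
    def is_baseline(self) -> bool:
        return self.mu01_d == self.mu01_s and self.mu10_d == self.mu10_s

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "ModelParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def to_dict(self) -> Dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def mu(self, event: str) -> Tuple[float, float]:
        """(gain, loss) pair for a branch whose parent node has ``event``."""
        if event == DUPLICATION:
            return self.mu01_d, self.mu10_d
        if event == SPECIATION:
            return self.mu01_s, self.mu10_s
        raise ValueError(f"unknown event class {event!r}")

    def transition_matrix(self, event: str) -> np.ndarray:
        """2x2 matrix T[parent_state, child_state]."""
        g, l = self.mu(event)
        return np.array([[1.0 - g, g], [l, 1.0 - l]])

    def error_matrix(self) -> np.ndarray:
        """2x2 matrix E[true_state, observed_state]."""
        return np.array([[1.0 - self.psi01, self.psi01],
                         [self.psi10, 1.0 - self.psi10]])


def leaf_error_prob(z: int, x: int, params: ModelParameters) -> float:
    """P(observed annotation z | true state x) under the mislabeling layer."""
    if z not in (0, 1) or x not in (0, 1):
        raise ValueError("states must be 0 or 1")
    return float(params.error_matrix()[x, z])


def transition_prob(x_child: int, x_parent: int, event: str,
                    params: ModelParameters) -> float:
    """P(child state | parent state) on a branch below an ``event`` node."""
    if x_child not in (0, 1) or x_parent not in (0, 1):
        raise ValueError("states must be 0 or 1")
    return float(params.transition_matrix(event)[x_parent, x_child])


def limiting_prob(mu01: float, mu10: float) -> float:
    """Stationary probability of function presence, mu01 / (mu01 + mu10).

    This is the long-run frequency of state 1 along an infinitely deep
    chain of branches sharing one (gain, loss) pair.
    """
    if mu01 + mu10 <= 0.0:
        raise ValueError("stationary distribution undefined when mu01 = mu10 = 0")
    return mu01 / (mu01 + mu10)


def limiting_prob_mixed(params: ModelParameters, p_dup: float) -> float:
    """Stationary presence probability mixed over event classes.

    ``p_dup`` is the observed proportion of duplication nodes among
    internal nodes of the tree at hand; each class contributes its own
    stationary value weighted by its frequency.
    """
    if not (0.0 <= p_dup <= 1.0):
        raise ValueError("p_dup must be a proportion")
    mu_d = limiting_prob(params.mu01_d, params.mu10_d)
    mu_s = limiting_prob(params.mu01_s, params.mu10_s)
    return mu_d * p_dup + mu_s * (1.0 - p_dup)


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior for one probability parameter."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shapes must be strictly positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def mode(self) -> float:
        if self.alpha > 1 and self.beta > 1:
            return (self.alpha - 1) / (self.alpha + self.beta - 2)
        raise ValueError("Beta mode undefined for shapes <= 1")

    def logpdf(self, x: float) -> float:
        if not (0.0 <= x <= 1.0):
            return -np.inf
        a, b = self.alpha, self.beta
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.log(x) if x > 0 else (-np.inf if a != 1 else 0.0)
            l1x = np.log1p(-x) if x < 1 else (-np.inf if b != 1 else 0.0)
        val = (a - 1) * lx + (b - 1) * l1x - betaln(a, b)
        return float(val) if np.isfinite(val) else -np.inf


class PriorSet:
    """Per-parameter Beta priors; a uniform prior is Beta(1, 1)."""

    def __init__(self, priors: Optional[Mapping[str, BetaPrior]] = None):
        self.priors: Dict[str, BetaPrior] = {n: BetaPrior(1.0, 1.0) for n in PARAM_NAMES}
        for name, prior in (priors or {}).items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            self.priors[name] = prior

    @classmethod
    def uniform(cls) -> "PriorSet":
        return cls()

    @classmethod
    def constant(cls, alpha: float, beta: float) -> "PriorSet":
        return cls({n: BetaPrior(alpha, beta) for n in PARAM_NAMES})

    @classmethod
    def informative(cls) -> "PriorSet":
        """Default informative priors: gain/loss after duplication likely
        high (Beta(9,2)); everything else likely low (Beta(2,9))."""
        return cls({
            "pi": BetaPrior(2, 9),
            "mu01_d": BetaPrior(9, 2), "mu10_d": BetaPrior(9, 2),
            "mu01_s": BetaPrior(2, 9), "mu10_s": BetaPrior(2, 9),
            "psi01": BetaPrior(2, 9), "psi10": BetaPrior(2, 9),
        })

    def __getitem__(self, name: str) -> BetaPrior:
        return self.priors[name]

    def log_density(self, params: ModelParameters) -> float:
        return sum(self.priors[n].logpdf(getattr(params, n)) for n in PARAM_NAMES)

    def means(self) -> ModelParameters:
        return ModelParameters.from_array([self.priors[n].mean for n in PARAM_NAMES])


# -- flat key-value serialization ---------------------------------------------

def params_to_yaml(params: ModelParameters) -> str:
    return yaml.safe_dump(params.to_dict(), sort_keys=False)


def params_from_yaml(text: str) -> ModelParameters:
    data = yaml.safe_load(text)
    return ModelParameters(**{n: float(data[n]) for n in PARAM_NAMES})


def priors_to_yaml(priors: PriorSet) -> str:
    flat = {}
    for name in PARAM_NAMES:
        flat[f"prior_{name}_alpha"] = float(priors[name].alpha)
        flat[f"prior_{name}_beta"] = float(priors[name].beta)
    return yaml.safe_dump(flat, sort_keys=False)


def priors_from_yaml(text: str) -> PriorSet:
    data = yaml.safe_load(text)
    priors = {}
    for name in PARAM_NAMES:
        a = data.get(f"prior_{name}_alpha", 1.0)
        b = data.get(f"prior_{name}_beta", 1.0)
        priors[name] = BetaPrior(float(a), float(b))
    return PriorSet(priors)
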