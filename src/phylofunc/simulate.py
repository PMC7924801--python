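"""Forward simulation of function evolution, observation error, and missingness.

The generator emulates the reconciled gene trees this model targets
(PANTHER-style families): random rooted bifurcating topologies built by
sequential random joins, with each internal node independently classed
as a duplication with probability ~0.2 — the duplication prevalence
typical of such trees — and speciation otherwise.  Function states
evolve root-to-leaves under the two-state model; annotations are then
corrupted by the mislabeling layer and thinned uniformly at random.

``run_scenario`` reproduces the Monte Carlo design used to validate the
estimator: per replicate, generating parameters are drawn from
scenario-specific Beta shapes, data are simulated and corrupted, the
model is refit by MCMC under both the generating ("correct") prior and a
biased prior (alpha doubled), and bias plus optional leave-one-out
prediction scores are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluate import mae, roc_auc
from .inference import MCMCSettings, mcmc, summarize
from .likelihood import AnnotatedTreeSet
from .model import PARAM_NAMES, BetaPrior, ModelParameters, PriorSet
from .prediction import loo_predictions
from .treeio import DUPLICATION, LEAF, SPECIATION, AnnotationSet, PhyloTree

#: Beta shapes of the data-generating process, by scenario parameter.
#: Gain after duplication is near-certain, loss after duplication is a
#: coin flip, and everything following speciation (and the root) is rare.
SCENARIO_SHAPES: Dict[str, Tuple[float, float]] = {
    "pi": (2, 38),
    "mu01_d": (38, 2),
    "mu10_d": (10, 10),
    "mu01_s": (2, 38),
    "mu10_s": (2, 38),
    "psi01": (2, 38),
    "psi10": (2, 38),
}

SCENARIOS = ("fully_annotated", "partial", "partial_mislabeled")


def simulate_tree(n_leaves: int, p_dup: float = 0.2, seed: int = 0) -> PhyloTree:
    """Random rooted bifurcating tree by sequential random joins.

    Each internal node is independently a duplication with probability
    ``p_dup``.  Leaves are labeled ``L0..L{n-1}``.
    """
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    rng = np.random.default_rng(seed)
    parents: List[Optional[int]] = [None] * n_leaves
    kinds = [LEAF] * n_leaves
    labels: List[Optional[str]] = [f"L{i}" for i in range(n_leaves)]
    roots = list(range(n_leaves))
    while len(roots) > 1:
        i, j = rng.choice(len(roots), size=2, replace=False)
        a, b = roots[i], roots[j]
        new = len(parents)
        parents.append(None)
        kinds.append(DUPLICATION if rng.random() < p_dup else SPECIATION)
        labels.append(None)
        parents[a] = new
        parents[b] = new
        # swap-remove the two joined roots, append the new one
        for r in sorted((i, j), reverse=True):
            roots[r] = roots[-1]
            roots.pop()
        roots.append(new)
    return PhyloTree.from_parents(parents, kinds, labels)


def simulate_states(tree: PhyloTree, params: ModelParameters,
                    seed: int = 0) -> Dict[int, int]:
    """Realize true function states at every node (root-to-leaves).

    The root is Bernoulli(pi); each child is drawn from the transition
    row selected by its realized parent state and the parent's event
    class.
    """
    rng = np.random.default_rng(seed)
    trans = {ev: params.transition_matrix(ev) for ev in (SPECIATION, DUPLICATION)}
    states: Dict[int, int] = {}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent_id is None:
            states[nid] = int(rng.random() < params.pi)
        else:
            pstate = states[node.parent_id]
            ev = tree.nodes[node.parent_id].kind
            states[nid] = int(rng.random() < trans[ev][pstate, 1])
    return states


def observe_states(truth: Dict[int, int], tree: PhyloTree,
                   params: ModelParameters, seed: int = 0,
                   function: str = "fn") -> AnnotationSet:
    """Apply the mislabeling layer to every leaf.

    A true 0 is flipped to an observed 1 with probability psi01 and a
    true 1 to 0 with probability psi10, independently per leaf.
    """
    rng = np.random.default_rng(seed)
    ann = AnnotationSet()
    for leaf in tree.leaves:
        x = truth[leaf.id]
        flip_p = params.psi01 if x == 0 else params.psi10
        z = 1 - x if rng.random() < flip_p else x
        ann[(leaf.label, function)] = z
    return ann


def drop_annotations(ann: AnnotationSet, proportion: float,
                     seed: int = 0) -> AnnotationSet:
    """Remove round(proportion * size) entries uniformly at random."""
    if not (0.0 <= proportion <= 1.0):
        raise ValueError("proportion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keys = sorted(ann.entries)
    n_drop = int(round(proportion * len(keys)))
    drop_idx = set(rng.choice(len(keys), size=n_drop, replace=False).tolist())
    return AnnotationSet({k: ann[k] for i, k in enumerate(keys) if i not in drop_idx})


@dataclass
class SimScenario:
    """One Monte Carlo study condition.

    ``scenario`` selects which corruption steps run: ``fully_annotated``
    keeps every leaf annotation and no mislabeling; ``partial`` drops a
    proportion m ~ Uniform(0.1, 0.9) of annotations; ``partial_mislabeled``
    additionally draws mislabeling probabilities from Beta(2, 38).
    ``missing_grid`` optionally fixes the missing proportions instead of
    drawing them (for binned summaries).
    """

    scenario: str = "fully_annotated"
    n_replicates: int = 10
    seed: int = 0
    shapes: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(SCENARIO_SHAPES))
    missing_low: float = 0.1
    missing_high: float = 0.9
    missing_grid: Optional[Sequence[float]] = None
    mcmc_settings: Optional[MCMCSettings] = None
    fit: bool = True
    score: bool = True
    #: which priors to fit under: "correct" (the generating shapes) and/or
    #: "biased" (alpha doubled)
    priors: Tuple[str, ...] = ("correct", "biased")

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _draw_params(shapes: Dict[str, Tuple[float, float]], scenario: str,
                 rng: np.random.Generator) -> ModelParameters:
    vals = {}
    for name in PARAM_NAMES:
        if name in ("psi01", "psi10") and scenario != "partial_mislabeled":
            vals[name] = 0.0
        else:
            a, b = shapes[name]
            vals[name] = float(rng.beta(a, b))
    return ModelParameters(**vals)


def _scenario_priors(shapes: Dict[str, Tuple[float, float]],
                     biased: bool = False) -> PriorSet:
    factor = 2.0 if biased else 1.0
    return PriorSet({n: BetaPrior(a * factor, b) for n, (a, b) in shapes.items()})


def run_scenario(scenario: SimScenario,
                 trees: Sequence[PhyloTree]) -> pd.DataFrame:
    """Execute the Monte Carlo study; one row per replicate.

    Each replicate draws its own generating parameters, simulates states
    and observations on a tree from ``trees`` (cycled), corrupts them per
    the scenario, refits by MCMC under the correct and the biased prior,
    and records truth, estimates, bias, and LOO prediction scores.  Fit
    failures are recorded in the ``error`` column rather than raised.
    """
    base_settings = scenario.mcmc_settings or MCMCSettings(
        n_iter=2000, n_chains=2, adapt_start=200)
    rows = []
    ss = np.random.SeedSequence(scenario.seed)
    rep_seeds = ss.spawn(scenario.n_replicates)
    for rep in range(scenario.n_replicates):
        rng = np.random.default_rng(rep_seeds[rep])
        tree = trees[rep % len(trees)]
        true = _draw_params(scenario.shapes, scenario.scenario, rng)
        truth = simulate_states(tree, true, seed=int(rng.integers(2**31)))
        ann = observe_states(truth, tree, true, seed=int(rng.integers(2**31)))
        if scenario.scenario == "fully_annotated":
            missing = 0.0
        else:
            if scenario.missing_grid is not None:
                missing = float(scenario.missing_grid[rep % len(scenario.missing_grid)])
            else:
                missing = float(rng.uniform(scenario.missing_low, scenario.missing_high))
            ann = drop_annotations(ann, missing, seed=int(rng.integers(2**31)))

        row: Dict[str, object] = {"replicate": rep, "scenario": scenario.scenario,
                                  "missing": missing, "n_annotated": len(ann),
                                  "error": ""}
        for name in PARAM_NAMES:
            row[f"true_{name}"] = getattr(true, name)

        if len(ann) == 0:
            row["error"] = "no annotations survived"
            rows.append(row)
            continue

        data = AnnotatedTreeSet()
        data.add(tree, ann, "fn")
        # mislabeling is fixed at its generating value (zero) in the
        # scenarios that exclude it
        fix = ({} if scenario.scenario == "partial_mislabeled"
               else {"psi01": 0.0, "psi10": 0.0})
        if scenario.fit:
            for tag in scenario.priors:
                priors = _scenario_priors(scenario.shapes, biased=(tag == "biased"))
                settings = MCMCSettings(
                    n_iter=base_settings.n_iter, n_chains=base_settings.n_chains,
                    adapt_start=base_settings.adapt_start, fix=fix)
                try:
                    trace = mcmc(data, priors, settings,
                                 seed=int(rng.integers(2**31)))
                    est = summarize(trace).point
                    for name in PARAM_NAMES:
                        row[f"est_{tag}_{name}"] = getattr(est, name)
                        row[f"bias_{tag}_{name}"] = (
                            getattr(true, name) - getattr(est, name))
                    if scenario.score:
                        loo = loo_predictions(tree, ann, est)
                        obs = loo["observed"].to_numpy()
                        pred = loo["posterior_prob"].to_numpy()
                        row[f"mae_{tag}"] = mae(obs, pred)
                        if 0 < obs.sum() < len(obs):
                            row[f"auc_{tag}"] = roc_auc(obs, pred)[0]
                except Exception as exc:  # recorded, not fatal
                    row["error"] = f"{tag}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
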