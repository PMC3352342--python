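"""Randomization significance test for virus-host co-divergence.

The observed virus tree is reconciled against the fixed host tree; its
Pareto-optimal solutions are then compared with reconciliations of random
virus trees (same leaves, same associations) onto the same host tree.  For
each observed solution two one-sided P-values are computed:

* ``p_ce``  -- proportion of random trees whose best reconciliation attains
  the same or a greater number of codivergence events (CEs);
* ``p_nce`` -- proportion attaining the same or a fewer number of
  non-codivergence events (NCEs = duplications + switches + losses).

Each random tree is summarized by its best achievable value per criterion
(its maximum CE, and separately its minimum NCE, over its own Pareto
front), i.e. the randomization is scored as favorably as possible under
each criterion.  Co-divergence is supported only if BOTH P-values fall
below ``alpha`` for some solution: the dual rule corrects for the more
sensitive NCE criterion relative to the CE criterion.

The null model draws virus topologies uniformly from labeled rooted binary
trees; a Yule (random-joining) model is available as a sensitivity switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconcile import (
    SolutionSet,
    best_codivergence,
    best_noncodivergence,
    reconcile,
)
from .trees import AssociationMap, PhyloTree, TreeNode

__all__ = [
    "PerSolutionResult",
    "RandomizationResult",
    "random_virus_trees",
    "randomization_test",
    "decide_significance",
]


@dataclass(frozen=True)
class PerSolutionResult:
    label: str
    ce: int
    nce: int
    p_ce: float
    p_nce: float
    significant: bool


@dataclass
class RandomizationResult:
    observed: SolutionSet
    null_ce: list[int]
    null_nce: list[int]
    p_ce: float  # P-values of the top-ranked (S1) solution
    p_nce: float
    n_randomizations: int
    alpha: float
    per_solution: list[PerSolutionResult]

    @property
    def supported(self) -> bool:
        """Overall verdict: co-divergence supported iff any solution passes
        both one-sided tests at alpha."""
        return any(r.significant for r in self.per_solution)


# ---------------------------------------------------------------------------
# random tree generation
# ---------------------------------------------------------------------------

def random_virus_trees(
    labels, n: int, seed, model: str = "uniform"
) -> list[PhyloTree]:
    """Draw ``n`` random rooted binary topologies on ``labels``.

    ``model='uniform'`` draws uniformly over the (2k-3)!! labeled rooted
    binary topologies via sequential leaf insertion on a uniformly chosen
    edge (counting the root edge).  ``model='yule'`` grows trees by random
    joining instead.  Reproducible: same seed, same list.
    """
    labels = sorted(set(labels))
    if len(labels) < 3:
        raise ValueError("need at least 3 leaf labels")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if model == "uniform":
        return [_uniform_tree(labels, rng) for _ in range(n)]
    if model == "yule":
        return [_yule_tree(labels, rng) for _ in range(n)]
    raise ValueError(f"unknown null model {model!r}")


def _uniform_tree(labels, rng) -> PhyloTree:
    root = TreeNode(label=labels[0])
    edges = [root]  # nodes whose parent edge (incl. the root edge) can be split
    for label in labels[1:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        leaf = TreeNode(label=label)
        joint = TreeNode(children=[target, leaf])
        if parent is None:
            root = joint
        else:
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
        edges.extend([joint, leaf])
    return PhyloTree(root)


def _yule_tree(labels, rng) -> PhyloTree:
    nodes = [TreeNode(label=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b]))
    return PhyloTree(nodes[0])


# ---------------------------------------------------------------------------
# the test itself
# ---------------------------------------------------------------------------

def randomization_test(
    virus: PhyloTree,
    host: PhyloTree,
    assoc: AssociationMap,
    n: int = 200,
    seed=0,
    alpha: float = 0.05,
    model: str = "uniform",
) -> RandomizationResult:
    """Run the dual-criterion randomization test.

    ``n`` defaults to 200 (the full analysis); subgroup analyses
    conventionally use 100.  The same association map is used for the
    observed and the random trees (topology-only randomization).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    observed = reconcile(virus, host, assoc)
    randoms = random_virus_trees(virus.leaf_labels(), n, seed, model=model)
    null_ce = [best_codivergence(t, host, assoc) for t in randoms]
    null_nce = [best_noncodivergence(t, host, assoc) for t in randoms]
    ce_arr = np.asarray(null_ce)
    nce_arr = np.asarray(null_nce)

    per_solution = []
    for sol in observed:
        p_ce = float(np.mean(ce_arr >= sol.ce))
        p_nce = float(np.mean(nce_arr <= sol.nce))
        per_solution.append(
            PerSolutionResult(
                label=sol.label,
                ce=sol.ce,
                nce=sol.nce,
                p_ce=p_ce,
                p_nce=p_nce,
                significant=bool(p_ce < alpha and p_nce < alpha),
            )
        )
    return RandomizationResult(
        observed=observed,
        null_ce=null_ce,
        null_nce=null_nce,
        p_ce=per_solution[0].p_ce,
        p_nce=per_solution[0].p_nce,
        n_randomizations=n,
        alpha=alpha,
        per_solution=per_solution,
    )


def decide_significance(result: RandomizationResult) -> dict[str, bool]:
    """Per-solution joint decision (both P-values below alpha).

    The overall verdict is ``result.supported``: co-divergence is supported
    iff any solution passes both tests.
    """
    return {r.label: r.significant for r in result.per_solution}
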