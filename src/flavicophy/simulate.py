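"""Synthetic data with known ground truth for every pipeline stage.

Three generators, each a pure function of its seed and parameters:

* :func:`simulate_cophylogeny` -- a host tree plus a virus tree grown down
  it by codivergence perturbed by duplications, host switches and losses at
  given per-divergence probabilities, with the true event history recorded;
* :func:`simulate_recombinant_alignment` -- two diverged parent sequences,
  a mosaic query with known breakpoints, and an outgroup;
* :func:`simulate_frameshift_sequence` -- a coding sequence whose premature
  in-frame stop is rescued by a stop-free +1 reading frame of known length.

Nucleotide evolution is a uniform (Jukes-Cantor-style) substitution
process: sufficient for the p-distance screens the data feed, with no rate
heterogeneity or indels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .reconcile import EventCount
from .screens import STOP_CODONS
from .trees import AssociationMap, PhyloTree, TreeNode

__all__ = [
    "CophylogenySimulation",
    "simulate_cophylogeny",
    "simulate_recombinant_alignment",
    "simulate_frameshift_sequence",
]

_BASES = np.array(list("ACGT"))


@dataclass
class CophylogenySimulation:
    host_tree: PhyloTree
    virus_tree: PhyloTree
    assoc: AssociationMap
    true_events: EventCount
    rates: tuple[float, float, float]  # (p_switch, p_duplication, p_loss)
    seed: int


def _uniform_host_tree(n_hosts: int, rng) -> PhyloTree:
    labels = [f"H{i + 1}" for i in range(n_hosts)]
    root = TreeNode(label=labels[0])
    edges = [root]
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


def simulate_cophylogeny(
    n_hosts: int,
    p_switch: float = 0.0,
    p_duplication: float = 0.0,
    p_loss: float = 0.0,
    seed: int = 0,
    max_attempts: int = 50,
) -> CophylogenySimulation:
    """Evolve a virus lineage down a simulated host tree.

    At each host divergence, each virus lineage present draws at most one
    event: a loss (the lineage follows only one host daughter), a host
    switch (the lineage diverges; one daughter follows a host child, the
    other jumps to a uniformly chosen incomparable host lineage), a
    duplication (two copies, which then both codiverge at this host node),
    or -- by default -- a codivergence.  With all rates zero the virus tree
    is topologically isomorphic to the host tree.

    Probabilities must satisfy p_switch + p_duplication + p_loss <= 1.
    Simulations whose virus tree ends up with fewer than 3 leaves are
    retried internally (bounded; the retry consumes the same rng stream so
    the result is still a pure function of the seed).
    """
    for p in (p_switch, p_duplication, p_loss):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if p_switch + p_duplication + p_loss > 1.0:
        raise ValueError("event probabilities sum to more than 1")
    if n_hosts < 3:
        raise ValueError("need at least 3 hosts")

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        host = _uniform_host_tree(n_hosts, rng)
        hnodes = list(host.postorder())
        desc: dict = {}
        for node in host.postorder():
            desc[id(node)] = {id(node)} | set().union(
                *(desc[id(c)] for c in node.children)
            ) if node.children else {id(node)}
        anc: dict = {id(n): set() for n in hnodes}
        for node in hnodes:
            for d in desc[id(node)]:
                anc[d].add(id(node))

        counts = {"ce": 0, "dup": 0, "switch": 0, "loss": 0}
        leaf_serial = itertools.count(1)
        leaves: list[tuple[str, str]] = []  # (virus label, host label)

        def incomparable_nodes(h):
            return [
                n
                for n in hnodes
                if id(n) not in desc[id(h)] and id(n) not in anc[id(h)]
            ]

        def evolve(h, allow_events=True) -> TreeNode | None:
            """Returns the virus subtree tracking host node ``h``."""
            if h.is_leaf:
                label = f"V{next(leaf_serial)}_{h.label}"
                leaves.append((label, h.label))
                return TreeNode(label=label)
            u = rng.random() if allow_events else 1.0
            if u < p_loss:
                counts["loss"] += 1
                child = h.children[rng.integers(2)]
                return evolve(child)
            if u < p_loss + p_switch:
                landing_sites = incomparable_nodes(h)
                if landing_sites:
                    counts["switch"] += 1
                    stay_child = h.children[rng.integers(2)]
                    land = landing_sites[rng.integers(len(landing_sites))]
                    stay = evolve(stay_child)
                    jump = evolve(land)
                    return TreeNode(children=[stay, jump])
                # no incomparable lineage (at the root): fall through
            if u < p_loss + p_switch + p_duplication:
                counts["dup"] += 1
                copy1 = evolve(h, allow_events=False)
                copy2 = evolve(h, allow_events=False)
                return TreeNode(children=[copy1, copy2])
            counts["ce"] += 1
            return TreeNode(
                children=[evolve(h.children[0]), evolve(h.children[1])]
            )

        root = evolve(host.root)
        if len(leaves) >= 3:
            virus = PhyloTree(root)
            return CophylogenySimulation(
                host_tree=host,
                virus_tree=virus,
                assoc=AssociationMap.from_pairs(leaves),
                true_events=EventCount(
                    counts["ce"], counts["dup"], counts["switch"], counts["loss"]
                ),
                rates=(p_switch, p_duplication, p_loss),
                seed=seed,
            )
    raise RuntimeError("could not simulate a >=3-leaf virus tree; lower p_loss")


# ---------------------------------------------------------------------------
# recombinant alignments
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, p: float, rng) -> np.ndarray:
    """Substitute each site with probability p to a uniformly chosen
    different base (Jukes-Cantor-style)."""
    out = seq.copy()
    hit = rng.random(len(seq)) < p
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def simulate_recombinant_alignment(
    parent_divergence: float = 0.2,
    breakpoints=(1500,),
    length: int = 3000,
    seed: int = 0,
):
    """A mosaic query between two diverged parents, plus an outgroup.

    The two parents each diverge ``parent_divergence/2`` from a common
    ancestor (so roughly ``parent_divergence`` from each other).  The query
    copies parent_major up to the first breakpoint, parent_minor to the
    next, alternating, with a small amount of query-specific noise (5 % of
    the parent divergence).  The outgroup sits at 1.5x the parent
    divergence.  All divergences scale with ``parent_divergence``: at zero,
    all four sequences are identical.

    Returns ``(records, truth)`` where records is an id -> sequence dict and
    truth records the breakpoints and per-segment donor parents.
    """
    breakpoints = sorted(breakpoints)
    if any(not 0 < b < length for b in breakpoints):
        raise ValueError("breakpoints must lie strictly within the alignment")
    rng = np.random.default_rng(seed)
    ancestor = _BASES[rng.integers(4, size=length)]
    half = parent_divergence / 2
    major = _mutate(ancestor, half, rng)
    minor = _mutate(ancestor, half, rng)
    outgroup = _mutate(ancestor, 1.5 * parent_divergence, rng)

    bounds = [0] + breakpoints + [length]
    query = major.copy()
    donors = []
    for k in range(len(bounds) - 1):
        donor = "parent_major" if k % 2 == 0 else "parent_minor"
        donors.append((bounds[k], bounds[k + 1], donor))
        if donor == "parent_minor":
            query[bounds[k] : bounds[k + 1]] = minor[bounds[k] : bounds[k + 1]]
    query = _mutate(query, 0.05 * parent_divergence, rng)

    records = {
        "query": "".join(query),
        "parent_major": "".join(major),
        "parent_minor": "".join(minor),
        "outgroup": "".join(outgroup),
    }
    truth = {"breakpoints": list(breakpoints), "segments": donors}
    return records, truth


# ---------------------------------------------------------------------------
# frameshift-rescuable sequences
# ---------------------------------------------------------------------------

def _random_nonstop_codon(rng) -> str:
    while True:
        codon = "".join(_BASES[rng.integers(4, size=3)])
        if codon not in STOP_CODONS:
            return codon


def simulate_frameshift_sequence(
    pre_stop_codons: int, post_shift_codons: int, seed: int = 0
):
    """A sequence with a premature frame-0 stop rescued in the +1 frame.

    Frame-0 translation runs stop-free for ``pre_stop_codons`` codons, then
    hits a stop.  From the recorded position (one nucleotide past the start
    of the stop codon, i.e. the +1 frame), translation is stop-free for at
    least ``post_shift_codons`` codons.

    Returns ``(sequence, truth)`` with truth holding ``stop_position``
    (codon index), ``rescue_start`` (nt) and ``rescued_codons``.
    """
    if pre_stop_codons < 1 or post_shift_codons < 1:
        raise ValueError("codon counts must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = "".join(_random_nonstop_codon(rng) for _ in range(pre_stop_codons))
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    rescue_start = 3 * pre_stop_codons + 1
    # Build the +1-frame tail codon by codon; the first +1 codon straddles
    # the stop codon's last two bases (never itself a stop: AAx/AGx/GAx).
    tail = stop[1:] + str(_BASES[rng.integers(4)])
    for _ in range(post_shift_codons - 1):
        tail += _random_nonstop_codon(rng)
    seq = prefix + stop[0] + tail
    truth = {
        "stop_position": pre_stop_codons,
        "rescue_start": rescue_start,
        "rescued_codons": post_shift_codons,
    }
    return seq, truth
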