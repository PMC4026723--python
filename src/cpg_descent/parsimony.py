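"""Fitch parsimony with ACCTRAN resolution for the binary CpG character.

The character is CpG presence (1) / absence (0) at the tips of a rooted
tree.  A Fitch downpass yields the minimum change count ``s``; among the
most-parsimonious reconstructions (MPRs) the accelerated-transformation
(ACCTRAN) resolution places changes as close to the root as possible, so
derived states arise early and homoplasy is expressed as later reversal.

ACCTRAN is realised here as an exact dynamic programme: among assignments
attaining ``s`` changes, maximise the total weight of change-bearing edges,
where an edge ending at depth ``d`` weighs ``2**(D - d)`` (``D`` = tree
depth).  Powers of two make the objective lexicographic in depth — a single
change moved one level rootward outweighs any rearrangement below it.  A
brute-force enumeration of all MPRs (feasible for these small trees) serves
as an independent oracle in the test suite.

Sites are retained for downstream origin assignment only when the character
is perfectly consistent (CI = 1) and the MPR is unique, i.e. the ancestral
states are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .calling import ABSENT, MISSING, PRESENT, PresenceVector
from .errors import DataError, UsageError
from .phylo import OUTGROUP_TAXON, PhyloTree

_STATE_CODE = {ABSENT: 0, PRESENT: 1}

#: Refuse exhaustive MPR enumeration beyond this many internal nodes.
MAX_ENUM_INTERNALS = 16


@dataclass
class ParsimonyResult:
    """Full reconstruction record for one site."""

    site_id: str
    downpass_sets: dict[str, frozenset[int]]
    final_states: dict[str, int]
    change_count: int  # s
    min_changes: int  # m: observed states - 1
    consistency_index: float  # m/s, 1.0 for invariant characters
    change_edges: frozenset[tuple[str, str]]
    unique_mpr: bool

    @property
    def retained(self) -> bool:
        """Unambiguous per the analysis filter: no homoplasy, unique MPR."""
        return self.consistency_index == 1.0 and self.unique_mpr


def _encode_states(tree: PhyloTree, states: PresenceVector) -> dict[str, int]:
    coded: dict[str, int] = {}
    for taxon in tree.taxa:
        state = states.states.get(taxon, MISSING)
        if state == MISSING:
            raise DataError(
                f"{states.site_id}: taxon {taxon} has missing state; "
                "reconcile_sources must drop such sites before parsimony"
            )
        coded[taxon] = _STATE_CODE[state]
    return coded


def fitch_downpass(
    tree: PhyloTree, states: PresenceVector
) -> tuple[dict[str, frozenset[int]], int]:
    """Standard Fitch downpass: per-node state sets and the change count."""
    coded = _encode_states(tree, states)
    sets: dict[str, frozenset[int]] = {}
    s = 0
    for node in tree.postorder():
        if node.is_leaf:
            sets[node.name] = frozenset({coded[node.name]})
            continue
        acc = None
        for child in node.children:
            cs = sets[child.name]
            if acc is None:
                acc = cs
            else:
                inter = acc & cs
                if inter:
                    acc = inter
                else:
                    acc = acc | cs
                    s += 1
        sets[node.name] = acc  # type: ignore[assignment]
    return sets, s


def _edge_weights(tree: PhyloTree) -> dict[str, int]:
    """Per-node weight of the edge entering the node, 2**(D - depth)."""
    depths = {tree.root.name: 0}
    for node in tree.preorder():
        for child in node.children:
            depths[child.name] = depths[node.name] + 1
    max_depth = max(depths.values())
    return {
        name: 1 << (max_depth - depth)
        for name, depth in depths.items()
        if name != tree.root.name
    }


def acctran_uppass(
    tree: PhyloTree,
    downpass_sets: dict[str, frozenset[int]],
    s: int,
    states: PresenceVector,
) -> ParsimonyResult:
    """Resolve one ACCTRAN reconstruction and classify MPR uniqueness.

    Runs an exact DP over (min changes, max root-proximal weight); the
    returned assignment is always an MPR, and ``unique_mpr`` reports whether
    it is the only one.
    """
    coded = _encode_states(tree, states)
    weights = _edge_weights(tree)

    INF = 10**9
    cost: dict[str, list[int]] = {}
    wbest: dict[str, list[int]] = {}
    count: dict[str, list[int]] = {}

    for node in tree.postorder():
        if node.is_leaf:
            c = coded[node.name]
            cost[node.name] = [0 if x == c else INF for x in (0, 1)]
            wbest[node.name] = [0, 0]
            count[node.name] = [1 if x == c else 0 for x in (0, 1)]
            continue
        node_cost, node_w, node_n = [0, 0], [0, 0], [1, 1]
        for parent_state in (0, 1):
            for child in node.children:
                w_edge = weights[child.name]
                options = [
                    (
                        cost[child.name][cs] + (1 if cs != parent_state else 0),
                        wbest[child.name][cs]
                        + (w_edge if cs != parent_state else 0),
                        count[child.name][cs],
                    )
                    for cs in (0, 1)
                ]
                best_cost = min(o[0] for o in options)
                best_w = max(o[1] for o in options if o[0] == best_cost)
                n_ways = sum(o[2] for o in options if o[0] == best_cost)
                node_cost[parent_state] += best_cost
                node_w[parent_state] += best_w
                node_n[parent_state] *= n_ways
        cost[node.name] = node_cost
        wbest[node.name] = node_w
        count[node.name] = node_n

    root = tree.root.name
    min_cost = min(cost[root])
    if min_cost != s:  # pragma: no cover - internal consistency
        raise UsageError(f"DP minimum {min_cost} disagrees with Fitch s={s}")

    # Outgroup polarisation: when the outgroup tip's state is attainable at
    # the root at minimum cost, the root is fixed to it and ambiguity is
    # judged among those reconstructions only.  This resolves the otherwise
    # symmetric "gain on the basal ingroup stem" vs "loss on the outgroup
    # edge" pair in favour of the ingroup gain, as outgroup comparison
    # dictates.  Trees without the canonical outgroup are left unconstrained.
    polarised = None
    if OUTGROUP_TAXON in coded and cost[root][coded[OUTGROUP_TAXON]] == min_cost:
        polarised = coded[OUTGROUP_TAXON]

    if polarised is not None:
        total_mprs = count[root][polarised]
        root_state = polarised
    else:
        total_mprs = sum(
            count[root][x] for x in (0, 1) if cost[root][x] == min_cost
        )
        # min cost, then max weight, then prefer the derived state (1)
        root_state = max(
            (x for x in (0, 1) if cost[root][x] == min_cost),
            key=lambda x: (wbest[root][x], x),
        )

    final: dict[str, int] = {root: root_state}
    for node in tree.preorder():
        parent_state = final[node.name]
        for child in node.children:
            w_edge = weights[child.name]
            options = [
                (
                    cost[child.name][cs] + (1 if cs != parent_state else 0),
                    wbest[child.name][cs] + (w_edge if cs != parent_state else 0),
                    cs,
                )
                for cs in (0, 1)
            ]
            best_cost = min(o[0] for o in options)
            # among min-cost choices: max weight, then prefer state 1
            final[child.name] = max(
                (o for o in options if o[0] == best_cost),
                key=lambda o: (o[1], o[2]),
            )[2]

    change_edges = frozenset(
        (node.name, child.name)
        for node in tree.preorder()
        for child in node.children
        if final[node.name] != final[child.name]
    )
    assert len(change_edges) == s

    observed = set(coded.values())
    m = len(observed) - 1
    ci = 1.0 if s == 0 else m / s
    return ParsimonyResult(
        site_id=states.site_id,
        downpass_sets=downpass_sets,
        final_states=final,
        change_count=s,
        min_changes=m,
        consistency_index=ci,
        change_edges=change_edges,
        unique_mpr=total_mprs == 1,
    )


def reconstruct(tree: PhyloTree, states: PresenceVector) -> ParsimonyResult:
    """Downpass + ACCTRAN uppass in one call."""
    sets, s = fitch_downpass(tree, states)
    return acctran_uppass(tree, sets, s, states)


def consistency_index(result: ParsimonyResult) -> float:
    """CI = (observed states − 1) / change count; 1 for invariant characters."""
    return result.consistency_index


def enumerate_mprs(
    tree: PhyloTree, states: PresenceVector
) -> list[dict[str, int]]:
    """All complete ancestral assignments attaining the minimum change count.

    Exhaustive over 2**(number of internal nodes); refuses trees beyond
    :data:`MAX_ENUM_INTERNALS` internals.  Intended as an independent oracle
    for the DP implementation and for ambiguity analysis at small scale.
    """
    coded = _encode_states(tree, states)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    if len(internals) > MAX_ENUM_INTERNALS:
        raise UsageError(
            f"{len(internals)} internal nodes exceeds exhaustive limit "
            f"{MAX_ENUM_INTERNALS}"
        )
    edges = [
        (node.name, child.name)
        for node in tree.preorder()
        for child in node.children
    ]
    best: list[dict[str, int]] = []
    best_cost = None
    for combo in product((0, 1), repeat=len(internals)):
        assign = dict(coded)
        assign.update({n.name: c for n, c in zip(internals, combo)})
        changes = sum(1 for p, c in edges if assign[p] != assign[c])
        if best_cost is None or changes < best_cost:
            best_cost = changes
            best = [assign]
        elif changes == best_cost:
            best.append(assign)
    return best


def filter_unambiguous(
    results: Iterable[ParsimonyResult],
) -> tuple[list[ParsimonyResult], list[tuple[str, str]]]:
    """Split reconstructions into retained and dropped-with-reason.

    Retained means CI = 1 and a unique MPR; drop reasons are ``homoplasy``
    (CI < 1) and ``ambiguous-mpr`` (multiple equally parsimonious
    reconstructions despite CI = 1).
    """
    retained: list[ParsimonyResult] = []
    dropped: list[tuple[str, str]] = []
    for result in results:
        if result.consistency_index < 1.0:
            dropped.append((result.site_id, "homoplasy"))
        elif not result.unique_mpr:
            dropped.append((result.site_id, "ambiguous-mpr"))
        else:
            retained.append(result)
    return retained, dropped
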