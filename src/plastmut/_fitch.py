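"""Small-parsimony (Sankoff) state mapping on the fixed dated topology.

Used to place a polymorphic character (a base, or the binary gapped/ungapped
indicator of a structural event) on a branch: dynamic programming gives the
minimum number of state changes, and backtracking enumerates every minimal
reconstruction's set of changed branches. A branch is identified by the name
of its child node.
"""

from __future__ import annotations

from .genomic_io import DatedTopology, TreeNode

MISSING = None
_INF = 10 ** 9


def sankoff_min_changes(
    topology: DatedTopology,
    leaf_states: dict[str, str | None],
    alphabet: tuple[str, ...],
) -> tuple[int, set[frozenset[tuple[str, str]]]]:
    """Minimum change count and the set of minimal changed-branch sets.

    ``leaf_states`` maps each tip to a state or ``None`` (missing: any state
    at zero cost). Each element of the returned set is a frozenset of
    ``(branch, derived_state)`` pairs for one minimal reconstruction.
    """
    cost: dict[str, dict[str, int]] = {}

    def up(node: TreeNode) -> None:
        if node.is_leaf:
            s = leaf_states.get(node.name, MISSING)
            cost[node.name] = {
                a: 0 if (s is MISSING or a == s) else _INF for a in alphabet
            }
            return
        for c in node.children:
            up(c)
        cost[node.name] = {
            a: sum(
                min(cost[c.name][b] + (a != b) for b in alphabet)
                for c in node.children
            )
            for a in alphabet
        }

    up(topology.root)
    root_cost = cost[topology.root.name]
    best = min(root_cost.values())

    def enumerate_assignments(
        node: TreeNode, state: str, changes: frozenset[tuple[str, str]]
    ) -> set[frozenset[tuple[str, str]]]:
        if node.is_leaf:
            return {changes}
        partial = {changes}
        for c in node.children:
            target = min(cost[c.name][b] + (state != b) for b in alphabet)
            nxt: set[frozenset[tuple[str, str]]] = set()
            for b in alphabet:
                if cost[c.name][b] + (state != b) != target:
                    continue
                delta = {(c.name, b)} if b != state else set()
                for p in partial:
                    nxt |= enumerate_assignments(c, b, p | delta)
            partial = nxt
        return partial

    results: set[frozenset[tuple[str, str]]] = set()
    for a in alphabet:
        if root_cost[a] == best:
            results |= enumerate_assignments(topology.root, a, frozenset())
    return best, results


def map_binary_character(
    topology: DatedTopology, leaf_states: dict[str, str | None]
) -> tuple[str | None, str, bool]:
    """Place a two-state character; returns (branch, rank, parallel).

    * exactly one minimal single-change placement -> that branch and its rank;
    * several tied single-change placements -> rank ``ambiguous``;
    * Fitch minimum >= 2 changes -> parallel mutation, rank ``ambiguous``.
    """
    from .genomic_io import RANK_AMBIGUOUS

    states = tuple(sorted({s for s in leaf_states.values() if s is not None}))
    if len(states) < 2:
        raise ValueError("character is not polymorphic among scored taxa")
    best, recons = sankoff_min_changes(topology, leaf_states, states)
    if best >= 2:
        return None, RANK_AMBIGUOUS, True
    branches = {next(iter(r))[0] for r in recons}
    if len(branches) == 1:
        b = branches.pop()
        return b, topology.branch_rank[b], False
    return None, RANK_AMBIGUOUS, False
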