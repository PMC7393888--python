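"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithmic machinery: parsimony by
exhaustive internal-state enumeration, inversion spans by exhaustive
substring scanning, coding effects by whole-gene translation.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def brute_force_min_changes(topology, leaf_states, alphabet):
    """Minimum change count and all minimal changed-branch sets, by
    enumerating every assignment of states to internal nodes."""
    internal = [n for n in topology.preorder() if not n.is_leaf]
    best = None
    recons = set()
    for combo in itertools.product(alphabet, repeat=len(internal)):
        state = {n.name: s for n, s in zip(internal, combo)}
        changes = set()
        cost = 0
        for n in topology.preorder():
            if n is topology.root:
                continue
            s = state[n.name] if n.name in state else leaf_states.get(n.name)
            if s is None:
                continue  # missing leaf matches anything at no cost
            parent_s = state[n.parent.name]
            if s != parent_s:
                cost += 1
                changes.add((n.name, s))
        if best is None or cost < best:
            best = cost
            recons = {frozenset(changes)}
        elif cost == best:
            recons.add(frozenset(changes))
    return best, recons


def brute_force_branch_call(topology, leaf_states, alphabet):
    """(branch, parallel) decision replicated from exhaustive enumeration."""
    best, recons = brute_force_min_changes(topology, leaf_states, alphabet)
    if best >= 2:
        return None, True
    branches = {next(iter(r))[0] for r in recons}
    if len(branches) == 1:
        return branches.pop(), False
    return None, False


def brute_force_revcomp_spans(ra: str, rb: str, min_total: int, max_total: int):
    """All maximal reverse-complement-equal spans (<= max_total columns)
    between two rows that contain at least one mismatch, by checking every
    substring pair."""
    n = len(ra)
    rc = str(Seq(rb).reverse_complement())  # rc[k] pairs with rb[n-1-k]
    clean = [ra[i] in "ACGT" and rb[i] in "ACGT" for i in range(n)]
    mm = [0] * (n + 1)  # prefix mismatch counts
    for i in range(n):
        mm[i + 1] = mm[i] + (1 if clean[i] and ra[i] != rb[i] else 0)
    hits = []
    for i in range(n):
        if not clean[i]:
            continue
        for j in range(i + min_total, min(n, i + max_total) + 1):
            if not clean[j - 1]:
                break
            if mm[j] > mm[i] and ra[i:j] == rc[n - j:n - i]:
                hits.append((i, j))
    maximal = [
        s for s in hits
        if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in hits)
    ]
    return sorted(set(maximal))


def stem_loop_split(sa: str, sb: str):
    """Edge agreement run between the two orientations -> (stem, loop)."""
    s = 0
    while s < len(sa) // 2 and sa[s] == sb[s]:
        s += 1
    return s, len(sa) - 2 * s


def whole_gene_effect(cds: str, offset: int, anc: str, der: str) -> str:
    """Synonymous/nonsynonymous by translating the entire ancestral and
    derived CDS (coding strand; plastid genetic code)."""
    anc_cds = cds[:offset] + anc + cds[offset + 1:]
    der_cds = cds[:offset] + der + cds[offset + 1:]
    pa = str(Seq(anc_cds).translate(table=11))
    pd = str(Seq(der_cds).translate(table=11))
    return "synonymous" if pa == pd else "nonsynonymous"
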