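"""Independent oracles used by the test suite.

Each oracle deliberately avoids the code path it checks: local alignment
is scored by exhaustive enumeration of monotone residue matchings, FRB
membership by literal evaluation of its definition over all pairs, depth
and overlap by per-position counting, and Dollo loss counts by exhaustive
minimisation over all single-gain/any-loss-subset assignments.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# local alignment: exhaustive enumeration over monotone matchings
#
# Any gapped local alignment is determined by its monotone set of aligned
# residue pairs; among all paths realising a given matching the best score
# charges each maximal unmatched run as one gap (open + length * extend),
# so maximising over matchings equals maximising over all alignment paths.


def brute_force_local_score(q: str, s: str, scheme) -> int:
    go, ge = scheme.gap_open, scheme.gap_extend
    eq = scheme.encode(q)
    es = scheme.encode(s)
    sub = scheme.matrix
    best = 0
    for k in range(1, min(len(q), len(s)) + 1):
        for qi in itertools.combinations(range(len(q)), k):
            for sj in itertools.combinations(range(len(s)), k):
                score = 0
                for a, b in zip(qi, sj):
                    score += int(sub[eq[a], es[b]])
                for t in range(k - 1):
                    dq = qi[t + 1] - qi[t] - 1
                    ds = sj[t + 1] - sj[t] - 1
                    if dq:
                        score += go + dq * ge
                    if ds:
                        score += go + ds * ge
                if score > best:
                    best = score
    return best


# ---------------------------------------------------------------------------
# FRB: literal membership definition over all (seed, subject) pairs


def brute_force_frb_members(
    forward: dict[str, dict[str, float]],
    reverse: dict[str, dict[str, float]],
    seed: str,
    fuzz: float,
) -> set[str]:
    """forward[seed][subject] / reverse[subject][seed] are best bitscores."""
    fwd = forward.get(seed, {})
    if not fwd:
        return set()
    fwd_top = max(fwd.values())
    members = set()
    for subject, bits in fwd.items():
        if bits < fuzz * fwd_top:
            continue
        rev = reverse.get(subject, {})
        if not rev or seed not in rev:
            continue
        if rev[seed] >= fuzz * max(rev.values()):
            members.add(subject)
    return members


# ---------------------------------------------------------------------------
# interval oracles: per-base / per-position counting


def per_base_overlap(exons_a, exons_b) -> int:
    points_a = set()
    for s, e in exons_a:
        points_a.update(range(s, e))
    shared = 0
    for s, e in exons_b:
        shared += sum(1 for p in range(s, e) if p in points_a)
    return shared


def per_position_depth(intervals, length: int) -> np.ndarray:
    depth = np.zeros(length, dtype=int)
    for s, e in intervals:  # 1-based inclusive
        for p in range(s, e + 1):
            depth[p - 1] += 1
    return depth


# ---------------------------------------------------------------------------
# rooted tree shapes and the exhaustive Dollo oracle


def rooted_shapes(n: int, binary_only: bool = True) -> list:
    """All rooted tree shapes with exactly n leaves, as canonical nested tuples."""
    if n == 1:
        return ["L"]
    shapes = set()
    max_parts = 2 if binary_only else n

    def partitions(total, max_first, min_parts):
        if total == 0:
            yield ()
            return
        for first in range(min(total, max_first), 0, -1):
            for rest in partitions(total - first, first, 0):
                yield (first,) + rest

    for parts in partitions(n, n - 1, 2):
        if len(parts) < 2 or len(parts) > max_parts:
            continue
        child_choices = [rooted_shapes(p, binary_only) for p in parts]
        for combo in itertools.product(*child_choices):
            shapes.add(tuple(sorted(combo, key=repr)))
    return sorted(shapes, key=repr)


def shape_to_newick(shape) -> tuple[str, list[str]]:
    """Label a shape's leaves L1..Ln in DFS order; return (newick, labels)."""
    labels = []

    def render(node):
        if node == "L":
            lab = f"L{len(labels) + 1}"
            labels.append(lab)
            return lab
        return "(" + ",".join(render(c) for c in node) + ")"

    return render(shape) + ";", labels


def tree_edge_masks(shape) -> tuple[int, list[int]]:
    """Bitmasks of the leaves below each edge (and each node), DFS leaf order.

    Returns (n_leaves, masks) where masks holds one leaf-set bitmask per
    tree node except the root (i.e. per edge, identified by its child).
    Node masks for internal use are included as well via the same list
    plus the full mask separately.
    """
    masks: list[int] = []
    counter = [0]

    def build(node, is_root):
        if node == "L":
            m = 1 << counter[0]
            counter[0] += 1
        else:
            m = 0
            for child in node:
                m |= build(child, False)
        if not is_root:
            masks.append(m)
        return m

    full = build(shape, True)
    return counter[0], masks, full


def dollo_min_losses_oracle(shape, pattern_bits: int):
    """Minimal losses over every single-gain/any-loss-subset assignment.

    Gain may sit on any node (equivalently the edge above it); losses are
    any subset of edges; a forward simulation realises the pattern iff
    mask(gain) minus the union of loss-edge leaves equals the pattern.
    Returns None when the pattern has no present leaf.
    """
    if pattern_bits == 0:
        return None
    n, edge_masks, full = tree_edge_masks(shape)
    gain_masks = edge_masks + [full]
    best = None
    n_edges = len(edge_masks)
    for gain in gain_masks:
        if pattern_bits & ~gain:
            continue
        for k in range(0, n + 1):
            if best is not None and k >= best:
                break
            found = False
            for subset in itertools.combinations(range(n_edges), k):
                union = 0
                for e in subset:
                    union |= edge_masks[e]
                if gain & ~union == pattern_bits:
                    found = True
                    break
            if found:
                if best is None or k < best:
                    best = k
                break
    return best


def dollo_oracle_all_patterns(shape) -> dict[int, int]:
    """Vectorised oracle: minimal losses for every achievable pattern.

    Enumerates all 2^E loss subsets once (union masks by subset DP) and,
    for every candidate gain node, groups subsets by the leaf pattern they
    realise, keeping the minimal subset size.
    """
    n, edge_masks, full = tree_edge_masks(shape)
    E = len(edge_masks)
    n_subsets = 1 << E
    unions = np.zeros(n_subsets, dtype=np.int64)
    popcnt = np.zeros(n_subsets, dtype=np.int64)
    for S in range(1, n_subsets):
        low = S & -S
        unions[S] = unions[S ^ low] | edge_masks[low.bit_length() - 1]
        popcnt[S] = popcnt[S ^ low] + 1
    best = np.full(1 << n, np.iinfo(np.int64).max, dtype=np.int64)
    for gain in edge_masks + [full]:
        present = gain & ~unions
        np.minimum.at(best, present, popcnt)
    return {p: int(best[p]) for p in range(1, 1 << n) if best[p] < np.iinfo(np.int64).max}
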