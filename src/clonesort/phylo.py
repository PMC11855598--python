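"""Maximum-parsimony trees from binary mutation presence/absence matrices.

Each sorted population is a leaf; an implicit all-zero germline outgroup
roots the tree. All tree topologies are enumerated exhaustively (feasible up
to 10 populations) and scored with Fitch's small-parsimony algorithm on
every mutation column; the minimum-score topology is reported, with ties
broken by the lexicographically smallest canonical Newick string. Branch
lengths are mutation counts: each mutation is mapped onto the edges where
its Fitch state assignment changes.

Trunk/branch classification follows two conventions exposed as modes:
``strict`` (default) calls a mutation trunk only when present in all
populations, shared when in two or more but not all, private when in exactly
one; ``biopsy`` calls trunk for presence in two or more populations and
private for exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_POPULATIONS = 10


def validate_presence_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("presence matrix entries must be 0/1")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 populations")
    if (vals.sum(axis=1) == 0).any():
        raise ValueError("presence matrix contains all-zero mutation rows")
    return matrix


# ---------------------------------------------------------------------------
# Topology enumeration (rooted binary trees as nested tuples of leaf names)
# ---------------------------------------------------------------------------

def _insert_everywhere(tree, leaf):
    """All trees obtained by attaching `leaf` on any edge of `tree` (or above
    its root)."""
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insert_everywhere(left, leaf):
            yield (t, right)
        for t in _insert_everywhere(right, leaf):
            yield (left, t)


def enumerate_topologies(leaves):
    """All (2n-3)!! rooted binary topologies over the given leaves."""
    leaves = list(leaves)
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t for base in trees for t in _insert_everywhere(base, leaf)]
    return trees


def _leafset(tree) -> frozenset:
    if not isinstance(tree, tuple):
        return frozenset([tree])
    return _leafset(tree[0]) | _leafset(tree[1])


# ---------------------------------------------------------------------------
# Fitch small parsimony (vectorised over deduplicated column patterns)
# ---------------------------------------------------------------------------

def _fitch_sets(tree, patterns: np.ndarray, col_of: dict):
    """Bottom-up Fitch pass. State sets are bitmasks over {absent=1, present=2}
    per pattern; returns (sets, changes) for the subtree root."""
    if not isinstance(tree, tuple):
        states = patterns[:, col_of[tree]]
        return np.where(states == 1, 2, 1).astype(np.int8), np.zeros(patterns.shape[0], int)
    lsets, lch = _fitch_sets(tree[0], patterns, col_of)
    rsets, rch = _fitch_sets(tree[1], patterns, col_of)
    inter = lsets & rsets
    union = lsets | rsets
    sets = np.where(inter > 0, inter, union).astype(np.int8)
    return sets, lch + rch + (inter == 0).astype(int)


def _fitch_score(tree, patterns: np.ndarray, counts: np.ndarray, col_of: dict) -> int:
    _, changes = _fitch_sets(tree, patterns, col_of)
    return int((changes * counts).sum())


def _fitch_assign(tree, patterns, col_of, parent_state, sets_cache, edge_changes, path=()):
    """Top-down Fitch refinement; tallies per-edge state changes per pattern.

    `parent_state` is an array of 0/1 per pattern; edges are keyed by the
    child clade's leaf set.
    """
    sets = sets_cache[path]
    parent_bit = np.where(parent_state == 1, 2, 1)
    state = np.where((sets & parent_bit) > 0, parent_state,
                     np.where((sets & 2) > 0, 1, 0))
    clade = _leafset(tree)
    edge_changes[clade] = (state != parent_state).astype(int)
    if isinstance(tree, tuple):
        _fitch_assign(tree[0], patterns, col_of, state, sets_cache, edge_changes, path + (0,))
        _fitch_assign(tree[1], patterns, col_of, state, sets_cache, edge_changes, path + (1,))


def _collect_sets(tree, patterns, col_of, cache, path=()):
    if not isinstance(tree, tuple):
        states = patterns[:, col_of[tree]]
        sets = np.where(states == 1, 2, 1).astype(np.int8)
        cache[path] = sets
        return sets
    l = _collect_sets(tree[0], patterns, col_of, cache, path + (0,))
    r = _collect_sets(tree[1], patterns, col_of, cache, path + (1,))
    inter = l & r
    sets = np.where(inter > 0, inter, l | r).astype(np.int8)
    cache[path] = sets
    return sets


# ---------------------------------------------------------------------------
# Newick rendering
# ---------------------------------------------------------------------------

def _canonical(tree):
    """Sort children recursively so topologically identical trees render to
    identical strings."""
    if not isinstance(tree, tuple):
        return tree
    kids = sorted((_canonical(tree[0]), _canonical(tree[1])), key=_tree_key)
    return (kids[0], kids[1])


def _tree_key(tree):
    return min(_leafset(tree))


def _render(tree, branch_len) -> str:
    clade = _leafset(tree)
    ln = branch_len.get(clade, 0)
    if not isinstance(tree, tuple):
        return f"{tree}:{ln}"
    return f"({_render(tree[0], branch_len)},{_render(tree[1], branch_len)}):{ln}"


@dataclass
class ParsimonyResult:
    newick: str                      # canonical minimum-score tree, rooted at germline
    score: int
    branch_counts: dict              # frozenset(leaves below edge) -> mutation count
    optimal_newicks: list            # all minimum-score topologies (canonical strings)
    n_topologies: int
    outgroup: str


def max_parsimony_tree(matrix: pd.DataFrame, outgroup: str = "germline") -> ParsimonyResult:
    """Exhaustive maximum-parsimony tree over a presence/absence matrix.

    An all-zero outgroup column is appended and the search enumerates every
    rooted binary topology over populations + outgroup. Raises for more than
    10 populations (the exhaustive bound; no heuristic mode is provided).
    """
    validate_presence_matrix(matrix)
    pops = list(matrix.columns)
    if len(pops) > MAX_POPULATIONS:
        raise ValueError(
            f"{len(pops)} populations exceeds the exhaustive-search bound of "
            f"{MAX_POPULATIONS}; a heuristic search would be required"
        )
    if outgroup in pops:
        raise ValueError(f"outgroup name {outgroup!r} collides with a population")

    full = matrix.copy()
    full[outgroup] = 0
    patterns, counts = np.unique(full.to_numpy(), axis=0, return_counts=True)
    col_of = {name: j for j, name in enumerate(full.columns)}

    # every unrooted topology over populations + outgroup corresponds to
    # exactly one rooted tree with the outgroup pendant at the root
    topologies = [(t, outgroup) for t in enumerate_topologies(pops)]
    scored = [(_fitch_score(t, patterns, counts, col_of), t) for t in topologies]
    best_score = min(s for s, _ in scored)
    optimal = [t for s, t in scored if s == best_score]
    rendered = [_render_with_counts(t, patterns, counts, col_of, outgroup) for t in optimal]
    rendered.sort(key=lambda nt: nt[0])
    # deduplicate topologies that differ only by internal rotations
    seen, optimal_newicks = set(), []
    for nwk, _ in rendered:
        if nwk not in seen:
            seen.add(nwk)
            optimal_newicks.append(nwk)
    newick, best_tree = rendered[0]
    branch_counts = _branch_counts(best_tree, patterns, counts, col_of)
    return ParsimonyResult(
        newick=newick, score=best_score,
        branch_counts={clade: int(v) for clade, v in branch_counts.items()},
        optimal_newicks=optimal_newicks,
        n_topologies=len(topologies), outgroup=outgroup,
    )


def _branch_counts(tree, patterns, counts, col_of) -> dict:
    tree = _canonical(tree)
    cache, edge_changes = {}, {}
    _collect_sets(tree, patterns, col_of, cache)
    root_state = np.zeros(patterns.shape[0], dtype=int)  # germline state at the root
    _fitch_assign(tree, patterns, col_of, root_state, cache, edge_changes)
    del edge_changes[_leafset(tree)]  # the root has no incoming edge
    return {clade: int((ch * counts).sum()) for clade, ch in edge_changes.items()}


def _render_with_counts(tree, patterns, counts, col_of, outgroup):
    tree = _canonical(tree)
    lens = _branch_counts(tree, patterns, counts, col_of)
    return _render(tree, lens) + ";", tree


# ---------------------------------------------------------------------------
# Trunk / branch / private classification
# ---------------------------------------------------------------------------

TRUNK_MODES = ("strict", "biopsy")


def classify_trunk(matrix: pd.DataFrame, mode: str = "strict") -> pd.Series:
    """Label each mutation trunk / shared / private from its presence pattern.

    ``strict``: trunk iff present in all populations, shared iff in >= 2 but
    not all, private iff exactly one. ``biopsy``: trunk iff present in >= 2
    populations, private iff exactly one (the within-biopsy convention).
    """
    if mode not in TRUNK_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {TRUNK_MODES}")
    validate_presence_matrix(matrix)
    npop = matrix.sum(axis=1)
    total = matrix.shape[1]
    if mode == "strict":
        labels = np.where(npop == total, "trunk",
                          np.where(npop >= 2, "shared", "private"))
    else:
        labels = np.where(npop >= 2, "trunk", "private")
    return pd.Series(labels, index=matrix.index, name="trunk_class")
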