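"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by brute force
(path enumeration, exhaustive null enumeration, Sankoff dynamic
programming, direct sums of squares) so the package code paths they check
are never used to produce the expected values.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phyloniche import read_newick, simulate_tree
from phyloniche.phylo_community import CommunityMatrix


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------
@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tree():
    return read_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture
def yule8():
    return simulate_tree(8, seed=8)


# --------------------------------------------------------------------------
# oracle: patristic distances by path enumeration
# --------------------------------------------------------------------------
def bfs_patristic_oracle(tree):
    """Tip-to-tip distances from an explicit node graph + BFS path sums."""
    adj = {}

    def add(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    label = {}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            label[id(node)] = node.taxon.label
        for child in node.child_nodes():
            add(id(node), id(child), child.edge.length or 0.0)
    tips = sorted(label, key=lambda k: label[k])
    names = [label[t] for t in tips]
    n = len(tips)
    out = np.zeros((n, n))
    for i, src in enumerate(tips):
        dist = {src: 0.0}
        frontier = [src]
        while frontier:
            u = frontier.pop()
            for v, w in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    frontier.append(v)
        for j, dst in enumerate(tips):
            out[i, j] = dist[dst]
    return pd.DataFrame(out, index=names, columns=names)


# --------------------------------------------------------------------------
# oracle: exhaustive enumeration of margin-preserving binary matrices
# --------------------------------------------------------------------------
def enumerate_margin_matrices(row_sums, col_sums):
    """All binary matrices with the given row and column totals."""
    n_cols = len(col_sums)
    out = []

    def rec(i, remaining, rows):
        if i == len(row_sums):
            if all(c == 0 for c in remaining):
                out.append(np.array(rows, dtype=np.int8))
            return
        rows_left = len(row_sums) - i - 1
        for cols in combinations(range(n_cols), row_sums[i]):
            ok = True
            for c in cols:
                if remaining[c] == 0:
                    ok = False
                    break
            if not ok:
                continue
            nxt = list(remaining)
            for c in cols:
                nxt[c] -= 1
            if any(v > rows_left for v in nxt):
                continue
            row = [0] * n_cols
            for c in cols:
                row[c] = 1
            rec(i + 1, nxt, rows + [row])

    rec(0, list(col_sums), [])
    return out


def pairwise_mpd_oracle(present_idx, dist):
    """Plain double-loop mean pairwise distance over present species."""
    pairs = [
        dist[i, j]
        for k, i in enumerate(present_idx)
        for j in present_idx[k + 1:]
    ]
    return float(np.mean(pairs))


def exhaustive_ses_oracle(presence, dist, plot_row):
    """Standardized effect size of one plot's MPD against the uniform
    distribution over every matrix with the observed margins."""
    mats = enumerate_margin_matrices(
        list(presence.sum(axis=1)), list(presence.sum(axis=0))
    )
    vals = []
    for m in mats:
        idx = list(np.flatnonzero(m[plot_row]))
        vals.append(pairwise_mpd_oracle(idx, dist))
    vals = np.array(vals)
    obs = pairwise_mpd_oracle(list(np.flatnonzero(presence[plot_row])), dist)
    return -(obs - vals.mean()) / vals.std(ddof=1), len(mats)


# --------------------------------------------------------------------------
# oracle: Sankoff unit-cost parsimony (recursive, dict-based)
# --------------------------------------------------------------------------
def sankoff_score_oracle(tree, tip_states):
    states = sorted(set(tip_states.values()))

    def cost(node):
        if node.is_leaf():
            return {
                s: (0 if s == tip_states[node.taxon.label] else float("inf"))
                for s in states
            }
        child_tables = [cost(c) for c in node.child_nodes()]
        table = {}
        for s in states:
            total = 0.0
            for ct in child_tables:
                total += min(
                    ct[t] + (0 if t == s else 1) for t in states
                )
            table[s] = total
        return table

    root_table = cost(tree.tree.seed_node)
    return min(root_table.values())


# --------------------------------------------------------------------------
# community fixtures
# --------------------------------------------------------------------------
def make_community(abundance_rows, species, sites):
    plots = [f"p{i + 1}" for i in range(len(abundance_rows))]
    ab = pd.DataFrame(abundance_rows, index=plots, columns=species)
    return CommunityMatrix(
        abundance=ab, sites=pd.Series(dict(zip(plots, sites)))
    )


@pytest.fixture
def small_community(balanced_four_tree):
    """3 plots x 4 species on the balanced tree, one site."""
    return make_community(
        [[2, 1, 0, 0], [0, 3, 1, 0], [1, 0, 2, 4]],
        ["a", "b", "c", "d"],
        ["s1", "s1", "s1"],
    )
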