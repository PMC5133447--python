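"""Independent reference implementations used only as test oracles.

Each oracle is written from the mathematical definition, separately from
the package's implementation path, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools


# ---------------------------------------------------------------------------
# Local affine-gap alignment


def sw_gotoh_score(q, t, matrix, gap_open, gap_extend):
    """Plain-Python Smith-Waterman-Gotoh best local score.

    Gap of length k costs gap_open + k * gap_extend (BLAST convention).
    """
    n, m = len(q), len(t)
    NEG = float("-inf")
    first = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = float(matrix[q[i - 1], t[j - 1]])
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(round(best))


def enumerate_local_score(q, t, matrix, gap_open, gap_extend):
    """Exhaustive enumeration of every gapped local alignment path.

    Exponential; only for very short sequences.  Validates the DP oracle.
    """
    n, m = len(q), len(t)
    first = gap_open + gap_extend
    best = 0.0

    def rec(i, j, score, last):
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            rec(i + 1, j + 1, score + float(matrix[q[i], t[j]]), "M")
        if i < n:
            rec(i + 1, j, score - (gap_extend if last == "D" else first), "D")
        if j < m:
            rec(i, j + 1, score - (gap_extend if last == "I" else first), "I")

    for i in range(n + 1):
        for j in range(m + 1):
            rec(i, j, 0.0, None)
    return int(round(best))


# ---------------------------------------------------------------------------
# Cluster partition


def cluster_partition_oracle(order, marker_gene_ids, contig_length, circular,
                             max_intervening, max_gap_bp):
    """Connected components of the pairwise chaining predicate.

    ``order``: features in rank order.  Two markers link when some arc
    between them carries <= max_intervening non-marker genes and <=
    max_gap_bp nucleotides.  Returns a frozenset of frozensets of gene ids.
    """
    n = len(order)
    idx = [i for i, f in enumerate(order) if f.gene_id in marker_gene_ids]
    marker_set = set(idx)

    def arc_ok(a, b):
        # forward arc from a to b
        if circular:
            ranks = [(a + k + 1) % n for k in range(((b - a - 1) % n))]
            a_end = order[a].end
            gap = (order[b].start - a_end) % contig_length
            if gap > contig_length - max(order[a].span(contig_length), 1):
                gap = 0
        else:
            if b < a:
                return False
            ranks = list(range(a + 1, b))
            gap = max(0, order[b].start - order[a].end)
        non_marker = sum(1 for r in ranks if r not in marker_set)
        return non_marker <= max_intervening and gap <= max_gap_bp

    def linked(a, b):
        return arc_ok(a, b) or arc_ok(b, a)

    parent = {i: i for i in idx}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(idx, 2):
        if linked(a, b):
            parent[find(a)] = find(b)
    groups = {}
    for i in idx:
        groups.setdefault(find(i), set()).add(order[i].gene_id)
    return frozenset(frozenset(g) for g in groups.values())


# ---------------------------------------------------------------------------
# Small-parsimony exhaustive minima


def all_labeled_trees(leaves):
    """Every rooted binary leaf-labeled topology over `leaves`, as nested tuples."""
    leaves = list(leaves)
    if len(leaves) == 1:
        return [leaves[0]]
    first, rest = leaves[0], leaves[1:]
    trees = []
    for r in range(len(rest)):
        for left_rest in itertools.combinations(rest, r):
            left_set = [first, *left_rest]
            right_set = [x for x in rest if x not in left_rest]
            if not right_set:
                continue
            for lt in all_labeled_trees(left_set):
                for rt in all_labeled_trees(right_set):
                    trees.append((lt, rt))
    return trees


def tree_shape(t):
    if not isinstance(t, tuple):
        return "*"
    return "(" + ",".join(sorted(tree_shape(c) for c in t)) + ")"


def to_newick(t):
    if not isinstance(t, tuple):
        return t
    return "(" + ",".join(to_newick(c) for c in t) + ")"


def _edges_and_nodes(t):
    """Flatten a nested-tuple tree: returns (node_list, edge_list, leaf_map).

    Nodes are integers; node 0 is the root; leaves carry their labels.
    """
    nodes, edges, leaf_of = [], [], {}
    counter = [0]

    def walk(sub, parent):
        my = counter[0]
        counter[0] += 1
        nodes.append(my)
        if parent is not None:
            edges.append((parent, my))
        if isinstance(sub, tuple):
            for c in sub:
                walk(c, my)
        else:
            leaf_of[my] = sub

    walk(t, None)
    return nodes, edges, leaf_of


def dollo_min_losses(t, pattern):
    """Minimum losses over every valid single-gain full labelling.

    `pattern`: dict leaf-name -> 0/1.  Returns None when no leaf is present
    (the character is never gained).
    """
    nodes, edges, leaf_of = _edges_and_nodes(t)
    if not any(pattern[name] for name in leaf_of.values()):
        return None
    internal = [v for v in nodes if v not in leaf_of]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = {v: s for v, s in zip(internal, assign)}
        for v, name in leaf_of.items():
            state[v] = pattern[name]
        gains = (1 if state[0] == 1 else 0) + sum(
            1 for p, c in edges if state[p] == 0 and state[c] == 1
        )
        if gains != 1:
            continue
        losses = sum(1 for p, c in edges if state[p] == 1 and state[c] == 0)
        if best is None or losses < best:
            best = losses
    return best


def fitch_min_changes(t, pattern):
    """Minimum state changes over every full labelling (reversible)."""
    nodes, edges, leaf_of = _edges_and_nodes(t)
    internal = [v for v in nodes if v not in leaf_of]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = {v: s for v, s in zip(internal, assign)}
        for v, name in leaf_of.items():
            state[v] = pattern[name]
        changes = sum(1 for p, c in edges if state[p] != state[c])
        if best is None or changes < best:
            best = changes
    return best


# ---------------------------------------------------------------------------
# Conserved-block trimming


def trim_kept_columns_oracle(rows, min_conserved, min_flank, max_gap_frac, min_block):
    """Straight-line restatement of the column/block keeping rules."""
    n_rows = len(rows)
    n_cols = len(rows[0]) if rows else 0
    status = []
    for j in range(n_cols):
        col = [r[j] for r in rows]
        gaps = sum(1 for c in col if c in "-.")
        residues = [c for c in col if c not in "-."]
        if not residues or gaps / n_rows > max_gap_frac:
            status.append("x")
            continue
        top = max(residues.count(c) for c in set(residues))
        if top / n_rows >= min_flank:
            status.append("H")
        elif top / n_rows >= min_conserved:
            status.append("c")
        else:
            status.append("x")
    kept = []
    j = 0
    while j < n_cols:
        if status[j] == "x":
            j += 1
            continue
        k = j
        while k < n_cols and status[k] != "x":
            k += 1
        block = list(range(j, k))
        while block and status[block[0]] != "H":
            block.pop(0)
        while block and status[block[-1]] != "H":
            block.pop()
        if len(block) >= min_block:
            kept.extend(block)
        j = k
    return kept
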