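"""p-distance and UPGMA against independent brute-force references."""

import numpy as np
import pytest

from pinpi._util import STANDARD_AA, ValidationError
from pinpi.cluster import (
    DistanceMatrix,
    p_distance,
    pairwise_matrix,
    to_newick,
    upgma,
)


# ---------------------------------------------------------------- oracles
def _oracle_align(a, b):
    """Plain recursive edit-distance alignment, memoized, same tie order
    (diagonal, then gap in b, then gap in a), resolved backwards from the
    full-sequence corner exactly as the production traceback is."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def cost(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            cost(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
            cost(i - 1, j) + 1,
            cost(i, j - 1) + 1,
        )

    i, j = len(a), len(b)
    cols = 0
    diffs = 0
    while i > 0 or j > 0:
        c = cost(i, j)
        if i > 0 and j > 0 and c == cost(i - 1, j - 1) + (a[i - 1] != b[j - 1]):
            diffs += a[i - 1] != b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and c == cost(i - 1, j) + 1:
            diffs += 1
            i -= 1
        else:
            diffs += 1
            j -= 1
        cols += 1
    return diffs, cols


def _oracle_upgma(labels, values):
    """UPGMA recomputed from scratch each step: cluster distance is the
    mean of the original leaf-pair distances."""
    idx = {lab: i for i, lab in enumerate(labels)}
    clusters = {lab: ((lab,), 0.0, lab) for lab in labels}  # members, height, newick-ish key
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                ma, mb = clusters[a][0], clusters[b][0]
                d = np.mean([values[idx[x], idx[y]] for x in ma for y in mb])
                key = (d, tuple(sorted((min(ma), min(mb)))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        ma, mb = clusters.pop(a), clusters.pop(b)
        name = min(a, b)
        clusters[name] = (ma[0] + mb[0], d / 2.0, name)
        merges.append((frozenset(ma[0]), frozenset(mb[0]), d / 2.0))
    return merges


def _collect_merges(node):
    out = []

    def walk(n):
        if n.is_leaf:
            return
        l, r = n.children
        out.append((frozenset(l.leaves()), frozenset(r.leaves()), n.height))
        walk(l)
        walk(r)

    walk(node)
    return out


def _canon(merges):
    """Order-free canonical form: (height, {left members, right members})."""
    return sorted(
        (round(h, 8), tuple(sorted((tuple(sorted(l)), tuple(sorted(r))))))
        for l, r, h in merges
    )


# ------------------------------------------------------------------ tests
def test_p_distance_examples():
    assert p_distance("ACDE", "ACDE") == 0.0
    assert p_distance("AAAA", "AAAT") == 0.25
    assert p_distance("AAAA", "AAA") == 0.25  # one gap column over length 4


def test_p_distance_rejects_empty():
    with pytest.raises(ValidationError):
        p_distance("", "AAA")


def test_p_distance_equals_edit_distance_oracle():
    rng = np.random.default_rng(23)
    for _ in range(150):
        la, lb = rng.integers(1, 21, size=2)
        a = "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=la))
        b = "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=lb))
        diffs, cols = _oracle_align(a, b)
        assert p_distance(a, b) == pytest.approx(diffs / cols)


def test_pairwise_matrix_properties():
    dm = pairwise_matrix({"a": "ACDE", "b": "ACDE"})
    assert dm.average_variance == 0.0

    dm = pairwise_matrix({"A": "AAAA", "B": "AAAT", "C": "TTTT"})
    assert dm.get("A", "B") == 0.25
    assert dm.get("A", "C") == 1.0
    assert dm.get("B", "C") == 0.75
    assert np.allclose(dm.values, dm.values.T)

    with pytest.raises(ValidationError):
        pairwise_matrix([("x", "AAAA"), ("x", "CCCC")])


def test_upgma_two_and_three_leaves():
    dm = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 0.2], [0.2, 0]]))
    root = upgma(dm)
    assert root.height == pytest.approx(0.1)
    assert sorted(root.leaves()) == ["A", "B"]

    vals = np.array([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]])
    root = upgma(DistanceMatrix(labels=["A", "B", "C"], values=vals))
    first, second = root.children
    assert sorted(first.leaves()) == ["A", "B"]
    assert first.height == pytest.approx(0.05)
    assert root.height == pytest.approx(0.2)


def test_upgma_invariant_to_label_order():
    rng = np.random.default_rng(5)
    n = 5
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    labels = [f"L{i}" for i in range(n)]
    base = to_newick(upgma(DistanceMatrix(labels=labels, values=v)))
    perm = rng.permutation(n)
    shuffled = DistanceMatrix(
        labels=[labels[i] for i in perm], values=v[np.ix_(perm, perm)]
    )
    assert to_newick(upgma(shuffled)) == base


def test_upgma_rejects_invalid_matrix():
    with pytest.raises(ValidationError):
        DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]]))


def test_upgma_equals_brute_force_reference():
    """Merge order and heights equal an exhaustive recomputation on random
    matrices up to n=6."""
    rng = np.random.default_rng(29)
    for _ in range(60):
        n = int(rng.integers(2, 7))
        v = rng.integers(1, 10, size=(n, n)).astype(float)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        labels = [f"t{i}" for i in range(n)]
        got = _canon(_collect_merges(upgma(DistanceMatrix(labels=labels, values=v))))
        want = _canon(_oracle_upgma(labels, v))
        assert got == want


def test_upgma_heights_are_ultrametric():
    rng = np.random.default_rng(41)
    for _ in range(20):
        n = int(rng.integers(3, 8))
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        root = upgma(DistanceMatrix(labels=[f"x{i}" for i in range(n)], values=v))

        def check(node):
            if node.is_leaf:
                return
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(root)


def test_newick_is_parseable_with_branch_lengths():
    from io import StringIO

    from Bio import Phylo

    vals = np.array([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]])
    nwk = to_newick(upgma(DistanceMatrix(labels=["A", "B", "C"], values=vals)))
    tree = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]
    depths = tree.depths()
    leaf_depths = [d for t, d in depths.items() if t.name]
    assert np.allclose(leaf_depths, leaf_depths[0])  # ultrametric tree


def test_shared_domains_mean_smaller_distance():
    """Among same-architecture precursors, genes built from more shared
    pool IRDs lie closer in p-distance (the basis of the dendrogram
    grouping by component domains)."""
    from scipy.stats import spearmanr

    from pinpi.synth import SyntheticConfig, generate_ird_pool, generate_precursors

    cfg = SyntheticConfig(
        seed=19, n_genes=16, n_unique_irds=8, n_cys_variants=0,
        architecture_probs=((3, 1.0),),
    )
    pool = generate_ird_pool(cfg)
    records, truth = generate_precursors(pool, cfg)
    seqs = {r.id: r.aa_seq for r in records}
    labels = {g["gene_id"]: g["ird_labels"] for g in truth["genes"]}
    dm = pairwise_matrix(seqs)
    shared, dist = [], []
    ids = list(seqs)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = labels[ids[i]], labels[ids[j]]
            shared.append(sum(x == y for x, y in zip(a, b)))
            dist.append(dm.get(ids[i], ids[j]))
    rho = spearmanr(shared, dist).statistic
    assert rho < -0.5  # more shared domains -> smaller distance
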