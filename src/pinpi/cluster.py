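"""Pairwise p-distances and UPGMA dendrograms over precursor sequences.

Distances are uncorrected p-distances computed on a global alignment with
unit edit costs (match 0, mismatch 1, gap 1): the distance is the number
of differing alignment columns divided by the alignment length.  The
traceback is deterministic, preferring diagonal moves, so the alignment
length (and hence the distance) is reproducible.  Trees are built with
UPGMA, which is ultrametric: node heights are half the average original
distance between the joined clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._util import ValidationError, check_sequence

__all__ = [
    "DistanceMatrix",
    "DendrogramNode",
    "align_global",
    "p_distance",
    "pairwise_matrix",
    "upgma",
    "to_newick",
]


def _edit_matrix(a: str, b: str) -> np.ndarray:
    """Full unit-cost edit-distance DP matrix, rows vectorized."""
    n, m = len(a), len(b)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    D[0] = np.arange(m + 1)
    cols = np.arange(m + 1)
    for i in range(1, n + 1):
        ai = ord(a[i - 1])
        tmp = np.minimum(D[i - 1, :-1] + (bb != ai), D[i - 1, 1:] + 1)
        # left moves are a running minimum: row[j] = min_{k<=j} t[k] + (j-k)
        t = np.concatenate(([i], tmp))
        D[i] = np.minimum.accumulate(t - cols) + cols
    return D


def align_global(a: str, b: str) -> tuple[str, str]:
    """Global alignment under unit edit costs with deterministic traceback.

    Traceback runs from the bottom-right corner preferring diagonal, then
    up (gap in ``b``), then left (gap in ``a``).
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    D = _edit_matrix(a, b)
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def p_distance(a: str, b: str) -> float:
    """Fraction of differing columns in the deterministic global alignment.

    Gap columns count as differences; identical sequences give 0.0.
    """
    a = check_sequence(a, name="sequence a")
    b = check_sequence(b, name="sequence b")
    aln_a, aln_b = align_global(a, b)
    diffs = sum(1 for x, y in zip(aln_a, aln_b) if x != y)
    return diffs / len(aln_a)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate labels in distance matrix")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("distance matrix diagonal is not zero")
        if (v < 0).any():
            raise ValidationError("distances must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    @property
    def average_variance(self) -> float:
        """Mean off-diagonal distance (the 'average variance' statistic)."""
        n = len(self)
        if n < 2:
            return 0.0
        iu = np.triu_indices(n, k=1)
        return float(self.values[iu].mean())

    def to_phylip(self) -> str:
        """PHYLIP square (lower+upper full) format."""
        lines = [f"    {len(self)}"]
        for lab, row in zip(self.labels, self.values):
            name = lab[:10].ljust(10)
            lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_matrix(sequences: Union[dict[str, str], Sequence[tuple[str, str]]]) -> DistanceMatrix:
    """All-pairs p-distance matrix; symmetric by construction.

    Accepts a mapping or a sequence of (id, aa_seq) pairs; duplicate ids
    are an error.  The mean off-diagonal distance is exposed as
    ``DistanceMatrix.average_variance``.
    """
    if isinstance(sequences, dict):
        items = list(sequences.items())
    else:
        items = list(sequences)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids")
    if len(items) < 2:
        raise ValidationError("need at least two sequences")
    n = len(items)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(items[i][1], items[j][1])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=ids, values=values)


@dataclass(frozen=True)
class DendrogramNode:
    """A leaf (label) or internal node (two children at a merge height)."""

    label: Optional[str] = None
    children: Optional[tuple["DendrogramNode", "DendrogramNode"]] = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()


def upgma(matrix: DistanceMatrix) -> DendrogramNode:
    """UPGMA agglomeration with a deterministic tie rule.

    At each step the pair of clusters with the smallest average original
    distance is merged at half that distance; among tied pairs the one
    whose (lexicographically smallest member, then second member) sorts
    first wins, so the result does not depend on input order.
    """
    n = len(matrix)
    if n < 2:
        raise ValidationError("need at least two leaves")
    # cluster state: representative = lexicographically smallest member
    clusters: dict[int, dict] = {
        i: {
            "node": DendrogramNode(label=lab),
            "members": [i],
            "rep": lab,
            "size": 1,
        }
        for i, lab in enumerate(matrix.labels)
    }
    D = matrix.values
    dist: dict[tuple[int, int], float] = {}
    keys = sorted(clusters)
    for ii in range(len(keys)):
        for jj in range(ii + 1, len(keys)):
            dist[(keys[ii], keys[jj])] = float(D[keys[ii], keys[jj]])
    next_id = n
    while len(clusters) > 1:
        best_key = None
        best = None
        for (i, j), d in dist.items():
            reps = tuple(sorted((clusters[i]["rep"], clusters[j]["rep"])))
            key = (d, reps)
            if best is None or key < best:
                best = key
                best_key = (i, j)
        i, j = best_key
        d = best[0]
        ci, cj = clusters.pop(i), clusters.pop(j)
        # put the lexicographically smaller representative first
        first, second = (ci, cj) if ci["rep"] <= cj["rep"] else (cj, ci)
        node = DendrogramNode(children=(first["node"], second["node"]), height=d / 2.0)
        new = {
            "node": node,
            "members": ci["members"] + cj["members"],
            "rep": min(ci["rep"], cj["rep"]),
            "size": ci["size"] + cj["size"],
        }
        # UPGMA update: unweighted average over all original leaf pairs
        new_dist: dict[tuple[int, int], float] = {}
        for (a, b), v in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(a, b)] = v
        for k, ck in clusters.items():
            total = sum(D[p, q] for p in new["members"] for q in ck["members"])
            new_dist[(min(k, next_id), max(k, next_id))] = total / (
                new["size"] * ck["size"]
            )
        clusters[next_id] = new
        dist = new_dist
        next_id += 1
    return next(iter(clusters.values()))["node"]


def to_newick(node: DendrogramNode, *, digits: int = 6) -> str:
    """Newick serialization with branch lengths (parent minus child height)."""

    def render(nd: DendrogramNode, parent_height: float) -> str:
        bl = parent_height - nd.height
        if nd.is_leaf:
            return f"{nd.label}:{bl:.{digits}f}"
        inner = ",".join(render(c, nd.height) for c in nd.children)
        return f"({inner}):{bl:.{digits}f}"

    if node.is_leaf:
        return f"{node.label};"
    inner = ",".join(render(c, node.height) for c in node.children)
    return f"({inner});"
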