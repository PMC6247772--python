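"""Hierarchical classification trees on between-species shape distances.

Species are agglomerated on their Mahalanobis distance matrix by single
linkage (minimum inter-cluster distance) or UPGMA (size-weighted average
linkage).  Node support comes from bootstrap resampling of specimens within
each species: the distance matrix and single-linkage tree are recomputed
for every replicate and each original internal node is scored by the
fraction of replicate trees containing the same leaf bipartition (clade
content, not heights).

Ties in the minimal linkage distance are broken by lexicographic cluster
label (a cluster is labelled by its sorted leaf names), so tree output is
deterministic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .discrimination import mahalanobis_matrix

logger = logging.getLogger("wingmorph")

__all__ = [
    "ClassificationTree",
    "TreeError",
    "single_linkage",
    "upgma",
    "bootstrap_tree",
    "to_newick",
    "from_newick",
]


class TreeError(ValueError):
    """Raised for invalid distance matrices or malformed Newick text."""


@dataclass
class ClassificationTree:
    """An agglomerative tree over species labels.

    ``merges`` lists, in order, (clade_a, clade_b, height) with clades as
    sorted tuples of leaf labels; the merged clade is their union.
    ``support`` maps each internal clade (frozenset of leaves) to its
    bootstrap fraction, and is only populated by :func:`bootstrap_tree`.
    """

    leaves: list
    merges: list
    method: str
    support: dict = field(default_factory=dict)

    @property
    def clades(self) -> list:
        """Internal-node clades (leaf frozensets), in merge order."""
        return [frozenset(a) | frozenset(b) for a, b, _ in self.merges]

    @property
    def bipartitions(self) -> set:
        """Non-trivial leaf bipartitions (clades excluding the root)."""
        all_leaves = frozenset(self.leaves)
        return {c for c in self.clades if c != all_leaves}

    def cophenetic(self, a: str, b: str) -> float:
        """Height of the first merge joining leaves a and b."""
        for ca, cb, h in self.merges:
            sa, sb = set(ca), set(cb)
            if (a in sa and b in sb) or (a in sb and b in sa):
                return h
        raise TreeError(f"leaves {a!r}, {b!r} never merged")


def _check_dist(dist: np.ndarray, labels: list) -> np.ndarray:
    d = np.asarray(dist, float)
    g = len(labels)
    if d.shape != (g, g):
        raise TreeError(f"distance matrix shape {d.shape} != ({g}, {g})")
    if not np.allclose(d, d.T, atol=1e-12):
        raise TreeError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise TreeError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise TreeError("distance matrix diagonal must be zero")
    if len(set(labels)) != g:
        raise TreeError("leaf labels must be unique")
    return d


def _agglomerate(dist: np.ndarray, labels: list, method: str) -> ClassificationTree:
    d = _check_dist(dist, labels)
    clusters: dict[tuple, list[int]] = {(lab,): [i] for i, lab in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for ca in clusters:
            for cb in clusters:
                if ca >= cb:
                    continue
                block = d[np.ix_(clusters[ca], clusters[cb])]
                link = block.min() if method == "single" else block.mean()
                key = (link, ca, cb)
                if best is None or key < best:
                    if best is not None and link == best[0]:
                        logger.info(
                            "linkage tie at %g between %s|%s and %s|%s: "
                            "lexicographic order applies",
                            link, best[1], best[2], ca, cb,
                        )
                    best = key
        link, ca, cb = best
        merges.append((ca, cb, float(link)))
        members = clusters.pop(ca) + clusters.pop(cb)
        clusters[tuple(sorted(ca + cb))] = members
    return ClassificationTree(leaves=sorted(labels), merges=merges, method=method)


def single_linkage(dist, labels) -> ClassificationTree:
    """Single-linkage (minimum inter-cluster distance) agglomeration."""
    return _agglomerate(dist, list(labels), "single")


def upgma(dist, labels) -> ClassificationTree:
    """UPGMA: size-weighted average-linkage agglomeration.

    Averaging over all member pairs weights clusters by size; on an
    ultrametric input matrix the merge heights reproduce it exactly.
    """
    return _agglomerate(dist, list(labels), "upgma")


def bootstrap_tree(
    shape_vars,
    labels,
    n_replicates: int = 100,
    seed: int = 20180611,
    var_fraction: float = 0.95,
) -> ClassificationTree:
    """Single-linkage tree with bootstrap support.

    Specimens are resampled with replacement within each species; the
    Mahalanobis matrix and single-linkage tree are recomputed per replicate
    and each original internal node is scored by the fraction of replicate
    trees containing the same leaf bipartition.
    """
    x = np.asarray(shape_vars, float)
    labels = np.asarray(labels)
    if n_replicates < 1:
        raise TreeError("need at least 1 bootstrap replicate")
    species = sorted(set(labels.tolist()))
    group_idx = {lab: np.nonzero(labels == lab)[0] for lab in species}
    for lab, idx in group_idx.items():
        if idx.size < 3:
            raise TreeError(f"species {lab!r} has {idx.size} specimens (minimum 3)")
    groups, d = mahalanobis_matrix(x, labels, var_fraction)
    tree = single_linkage(d, groups)
    counts = {c: 0 for c in tree.clades}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        take = np.concatenate(
            [rng.choice(group_idx[lab], size=group_idx[lab].size) for lab in species]
        )
        rep_groups, rep_d = mahalanobis_matrix(x[take], labels[take], var_fraction)
        rep_clades = set(single_linkage(rep_d, rep_groups).clades)
        for c in counts:
            if c in rep_clades:
                counts[c] += 1
    tree.support = {c: counts[c] / n_replicates for c in counts}
    return tree


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------

def to_newick(tree: ClassificationTree, digits: int = 6) -> str:
    """Serialize as Newick with bootstrap supports as internal-node labels
    and branch lengths as height differences (leaves at height 0)."""

    reps: dict[tuple, tuple[str, float]] = {
        (lab,): (lab, 0.0) for lab in tree.leaves
    }
    text, height = "", 0.0
    for ca, cb, h in tree.merges:
        (ta, ha), (tb, hb) = reps.pop(ca), reps.pop(cb)
        merged = tuple(sorted(ca + cb))
        sup = tree.support.get(frozenset(merged))
        label = f"{sup:.{digits}g}" if sup is not None else ""
        text = (
            f"({ta}:{h - ha:.{digits}g},{tb}:{h - hb:.{digits}g}){label}"
        )
        reps[merged] = (text, h)
        height = h
    (text, _), = reps.values()
    return text + ";"


def from_newick(text: str) -> ClassificationTree:
    """Parse a Newick string written by :func:`to_newick`.

    Heights are reconstructed from branch lengths assuming leaves sit at
    height 0 (as the writer guarantees); supports are read from internal
    node labels when present.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("Newick text must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node():
        nonlocal pos
        children = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                children.append(parse_node())
                if pos >= len(s):
                    raise TreeError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise TreeError(f"unexpected character {s[pos]!r} at {pos}")
        m = re.match(r"[^(),;:]*", s[pos:])
        label = m.group(0)
        pos += len(label)
        length = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[^(),;:]+", s[pos:])
            if not m:
                raise TreeError(f"missing branch length at {pos}")
            length = float(m.group(0))
            pos += len(m.group(0))
        return {"children": children, "label": label, "length": length}

    root = parse_node()
    if pos != len(s):
        raise TreeError(f"trailing characters after position {pos}")

    merges = []
    support = {}

    def walk(node):
        """Return (clade tuple, height)."""
        if not node["children"]:
            if not node["label"]:
                raise TreeError("leaf without a name")
            return (node["label"],), 0.0
        parts = [walk(c) for c in node["children"]]
        if len(parts) != 2:
            raise TreeError("only binary trees are supported")
        (ca, ha), (cb, hb) = parts
        la = ha + node["children"][0]["length"]
        lb = hb + node["children"][1]["length"]
        # branch lengths are printed at 6 significant digits, so sibling
        # heights can disagree by accumulated rounding
        if abs(la - lb) > 1e-4 * max(1.0, abs(la)):
            raise TreeError("non-ultrametric branch lengths")
        if ca > cb:
            ca, cb, ha, hb = cb, ca, hb, ha
        h = 0.5 * (la + lb)
        merges.append((ca, cb, h))
        merged = tuple(sorted(ca + cb))
        if node["label"]:
            support[frozenset(merged)] = float(node["label"])
        return merged, h

    clade, _ = walk(root)
    merges.sort(key=lambda m: (m[2], m[0], m[1]))
    return ClassificationTree(
        leaves=sorted(clade), merges=merges, method="parsed", support=support
    )
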