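"""Analytics over a binary species x ethnic-group use matrix.

Covers composition/uniqueness tabulation, use-frequency spectra, the
binary A/C sequence coding, p-distances, and distance-based cluster trees
of the groups (neighbor joining or average linkage), optionally rooted on
user-supplied outgroup rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

SUBSETS = ("all", "endemic", "threatened")


def _subset_matrix(U: pd.DataFrame, subset: str, traits: pd.DataFrame | None):
    if subset == "all":
        return U
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    if traits is None:
        raise ValueError(f"subset {subset!r} requires a trait table")
    t = traits.set_index("species") if "species" in traits.columns else traits
    keep = [s for s in U.index if s in t.index and bool(t.at[s, subset])]
    return U.loc[keep]


def group_composition(
    U: pd.DataFrame, subset: str = "all", traits: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-group species totals, unique counts (species used by that group
    alone), and shared counts (species used by >= 2 groups)."""
    M = _subset_matrix(U, subset, traits)
    vals = M.to_numpy(dtype=int)
    k = vals.sum(axis=1)  # groups per species
    total = vals.sum(axis=0)
    unique = ((k == 1)[:, None] & (vals == 1)).sum(axis=0)
    shared = ((k >= 2)[:, None] & (vals == 1)).sum(axis=0)
    return pd.DataFrame(
        {"group": M.columns, "total": total, "unique": unique, "shared": shared}
    ).set_index("group")


def use_frequency_distribution(
    U: pd.DataFrame, subset: str = "all", traits: pd.DataFrame | None = None
) -> pd.Series:
    """Counts of species used by exactly k groups, k = 1..n_groups."""
    M = _subset_matrix(U, subset, traits)
    k = M.to_numpy(dtype=int).sum(axis=1)
    n_groups = M.shape[1]
    counts = np.bincount(k, minlength=n_groups + 1)[1 : n_groups + 1]
    return pd.Series(counts, index=pd.RangeIndex(1, n_groups + 1, name="k"))


# ---------------------------------------------------------------------------
# Sequence coding
# ---------------------------------------------------------------------------


@dataclass
class CodedSequences:
    """Per-group A/C strings over a fixed species ordering (1 = A, 0 = C)."""

    species_order: list[str]
    sequences: dict[str, str]

    def __post_init__(self):
        L = len(self.species_order)
        for g, s in self.sequences.items():
            if len(s) != L:
                raise ValueError(f"sequence for {g!r} has wrong length")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for g, s in self.sequences.items():
                fh.write(f">{g}\n{s}\n")

    def to_nexus(self, path) -> None:
        names = list(self.sequences)
        L = len(self.species_order)
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(names)} NCHAR={L};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
            width = max(len(n) for n in names) + 2
            for g in names:
                fh.write(f"    {g.ljust(width)}{self.sequences[g]}\n")
            fh.write("  ;\nEND;\n")


def encode_sequences(
    U: pd.DataFrame, outgroups: pd.DataFrame | None = None
) -> CodedSequences:
    """Translate the use matrix (groups as columns) into per-group A/C
    strings; optional outgroups are extra group-rows with the same species
    ordering."""
    species_order = list(U.index)
    seqs = {}
    vals = U.to_numpy(dtype=int)
    for j, g in enumerate(U.columns):
        seqs[str(g)] = "".join("A" if v else "C" for v in vals[:, j])
    if outgroups is not None:
        og = outgroups[species_order] if list(outgroups.columns) != species_order else outgroups
        for name, row in og.iterrows():
            seqs[str(name)] = "".join("A" if v else "C" for v in row.to_numpy(dtype=int))
    return CodedSequences(species_order=species_order, sequences=seqs)


def decode_sequences(C: CodedSequences) -> pd.DataFrame:
    """Inverse of :func:`encode_sequences` (species x group 0/1 matrix)."""
    data = {
        g: [1 if ch == "A" else 0 for ch in s] for g, s in C.sequences.items()
    }
    return pd.DataFrame(data, index=C.species_order)


def use_distance_matrix(C: CodedSequences) -> pd.DataFrame:
    """Pairwise p-distance (Hamming / length) between coded sequences."""
    names = list(C.sequences)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array(
        [[1 if ch == "A" else 0 for ch in C.sequences[g]] for g in names], dtype=int
    )
    L = arr.shape[1]
    diff = (arr[:, None, :] != arr[None, :, :]).sum(axis=2) / L
    return pd.DataFrame(diff, index=names, columns=names)


# ---------------------------------------------------------------------------
# Cluster trees
# ---------------------------------------------------------------------------


@dataclass
class GroupTree:
    tree: TreeNode
    method: str
    outgroups: list[str]

    def newick(self) -> str:
        return str(self.tree).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial tip bipartitions, each as the smaller/canonical side."""
        tips = frozenset(t.name for t in self.tree.tips())
        splits = set()
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(tips) - 1:
                other = tips - side
                splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits


def build_cluster_tree(
    D: pd.DataFrame,
    method: str = "nj",
    outgroup_ids: list[str] | None = None,
) -> GroupTree:
    """Distance-based group tree.

    ``method`` is ``"nj"`` (neighbor joining) or ``"average"`` (UPGMA-style
    average linkage).  When outgroup ids are given the NJ tree is re-rooted
    on their branch.  Deterministic for fixed input.
    """
    names = list(D.index)
    if method == "nj":
        if len(names) < 3:
            raise ValueError("neighbor joining needs at least 3 taxa")
        dm = DistanceMatrix(D.to_numpy(dtype=float), ids=[str(n) for n in names])
        tree = nj(dm)
    elif method == "average":
        if len(names) < 2:
            raise ValueError("need at least 2 taxa")
        from scipy.spatial.distance import squareform

        Z = linkage(squareform(D.to_numpy(dtype=float), checks=False),
                    method="average")
        tree = TreeNode.from_linkage_matrix(Z, [str(n) for n in names])
    else:
        raise ValueError(f"unknown method {method!r}")

    outgroups = [str(o) for o in (outgroup_ids or [])]
    if outgroups:
        if len(outgroups) == 1:
            node = tree.find(outgroups[0])
            tree = tree.root_at(node.parent)
        else:
            lca = tree.lowest_common_ancestor(outgroups)
            if not lca.is_root():
                tree = tree.root_at(lca)
    return GroupTree(tree=tree, method=method, outgroups=outgroups)
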