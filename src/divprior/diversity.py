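"""Diversity surfaces over a presence matrix.

Implements six per-cell quantities:

* SR — species richness;
* SC_rank — greedy complementarity selection order, encoded as a surface;
* WE — weighted endemism (sum of inverse range sizes);
* PD — Faith phylogenetic diversity, root path included;
* PE — phylogenetic endemism (branch lengths down-weighted by the cell
  range of the branch's descendant clade);
* PA — composite PD/PD_max + PE/PE_max.

PD/PE conventions: branch lengths are summed over the minimal subtree
connecting a cell's species to the supplied root.  Branch ranges for PE
are computed on the analysis grid.  Species missing from the tree are
excluded from PD/PE only (they still count for SR/WE/SC); the exclusion is
recorded in the surface provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from .occurrences import PresenceMatrix


@dataclass
class MetricSurface:
    """One value per land cell for a named metric."""

    name: str
    cell_ids: np.ndarray
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_ids.shape != self.values.shape:
            raise ValueError("cell ids and values differ in length")

    def value_of(self, cell_id) -> float:
        j = int(np.flatnonzero(self.cell_ids == cell_id)[0])
        return float(self.values[j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"cell_id": self.cell_ids, self.name: self.values})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _provenance(P: PresenceMatrix, **extra) -> dict:
    h = hashlib.sha256(P.matrix.tobytes()).hexdigest()[:16]
    return {"presence_hash": h, "n_species": P.n_species, "n_cells": P.n_cells, **extra}


# ---------------------------------------------------------------------------
# SR / WE
# ---------------------------------------------------------------------------


def species_richness(P: PresenceMatrix) -> MetricSurface:
    if P.n_species == 0:
        raise ValueError("empty presence matrix")
    sr = P.matrix.sum(axis=0).astype(float)
    return MetricSurface("SR", P.cell_ids, sr, _provenance(P))


def weighted_endemism(P: PresenceMatrix) -> MetricSurface:
    """WE(cell) = sum over species present of 1 / range size."""
    rs = P.range_sizes().astype(float)
    if np.any(rs < 1):
        raise ValueError("presence matrix contains a species with empty range")
    we = (1.0 / rs) @ P.matrix
    return MetricSurface("WE", P.cell_ids, we, _provenance(P))


# ---------------------------------------------------------------------------
# Greedy complementarity (set cover)
# ---------------------------------------------------------------------------


@dataclass
class ComplementarityResult:
    selected_cells: list[int]  # cell ids in selection order
    marginal_gains: list[int]
    cover_size: int
    sc_rank: MetricSurface  # higher value = selected earlier; 0 = unselected

    def selection_rank(self, cell_id) -> int:
        """1 = first selected; 0 = not selected."""
        try:
            return self.selected_cells.index(int(cell_id)) + 1
        except ValueError:
            return 0


def complementarity(P: PresenceMatrix) -> ComplementarityResult:
    """Greedy minimum-set-cover selection of cells.

    Repeatedly pick the cell adding the most currently-unrepresented
    species; ties broken by higher total SR, then lower cell id.  The
    SC_rank surface scores selected cells in descending selection order
    (first pick highest) so the surface participates in top-fraction
    thresholding like any other metric.
    """
    if P.n_species == 0:
        raise ValueError("empty presence matrix")
    if np.any(P.range_sizes() == 0):
        raise ValueError("species with zero occurrences violates the contract")

    M = P.matrix
    sr_total = M.sum(axis=0)
    uncovered = np.ones(P.n_species, dtype=bool)
    selected: list[int] = []
    selected_j: list[int] = []
    gains: list[int] = []
    while uncovered.any():
        gain = M[uncovered].sum(axis=0)
        if len(selected_j):
            gain[np.asarray(selected_j)] = -1
        best = np.max(gain)
        cand = np.flatnonzero(gain == best)
        # tie break: higher total SR, then lower cell id (ascending order)
        cand = cand[np.lexsort((P.cell_ids[cand], -sr_total[cand]))]
        j = int(cand[0])
        selected_j.append(j)
        selected.append(int(P.cell_ids[j]))
        gains.append(int(best))
        uncovered &= ~M[:, j]

    k = len(selected)
    values = np.zeros(P.n_cells, dtype=float)
    for order, j in enumerate(selected_j):
        values[j] = k - order  # first selected gets the highest score
    surface = MetricSurface(
        "SC_rank", P.cell_ids, values, _provenance(P, cover_size=k)
    )
    return ComplementarityResult(
        selected_cells=selected, marginal_gains=gains, cover_size=k, sc_rank=surface
    )


# ---------------------------------------------------------------------------
# Phylogenetic metrics
# ---------------------------------------------------------------------------


def load_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def _edge_tables(tree: dendropy.Tree, species_ids: list[str]):
    """Edge lengths and edge x species descendant-incidence matrix.

    Edges with no matched descendant tip are kept (they simply never
    contribute).  Returns (lengths, incidence, matched_species_mask).
    """
    s_index = {s: i for i, s in enumerate(species_ids)}
    matched = np.zeros(len(species_ids), dtype=bool)
    lengths = []
    rows = []
    # postorder: accumulate descendant tip sets bottom-up
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips = np.zeros(len(species_ids), dtype=bool)
            label = node.taxon.label if node.taxon else None
            if label in s_index:
                tips[s_index[label]] = True
                matched[s_index[label]] = True
            below[node] = tips
        else:
            tips = np.zeros(len(species_ids), dtype=bool)
            for ch in node.child_nodes():
                tips |= below[ch]
            below[node] = tips
        length = node.edge.length
        if length is None:
            length = 0.0
        lengths.append(float(length))
        rows.append(below[node])
    return np.asarray(lengths), np.vstack(rows), matched


def _phylo_surfaces(P: PresenceMatrix, tree: dendropy.Tree):
    lengths, inc, matched = _edge_tables(tree, P.species_ids)
    if not matched.any():
        raise ValueError("no species in common between tree and presence matrix")
    # edge x cell: does any descendant tip of the edge occur in the cell?
    M = (inc @ P.matrix) > 0
    pd_vals = lengths @ M
    ranges = M.sum(axis=1).astype(float)
    w = np.divide(lengths, ranges, out=np.zeros_like(lengths), where=ranges > 0)
    pe_vals = w @ M
    unmatched = [s for s, m in zip(P.species_ids, matched) if not m]
    return pd_vals, pe_vals, unmatched, float(lengths.sum())


def phylogenetic_diversity(P: PresenceMatrix, tree: dendropy.Tree) -> MetricSurface:
    pd_vals, _, unmatched, total = _phylo_surfaces(P, tree)
    prov = _provenance(
        P, unmatched_species=unmatched, total_tree_length=total,
        root_path="included",
    )
    return MetricSurface("PD", P.cell_ids, pd_vals, prov)


def phylogenetic_endemism(P: PresenceMatrix, tree: dendropy.Tree) -> MetricSurface:
    _, pe_vals, unmatched, total = _phylo_surfaces(P, tree)
    prov = _provenance(
        P, unmatched_species=unmatched, total_tree_length=total,
        branch_range="analysis_grid", root_path="included",
    )
    return MetricSurface("PE", P.cell_ids, pe_vals, prov)


def pa_index(pd_surface: MetricSurface, pe_surface: MetricSurface) -> MetricSurface:
    """PA(cell) = PD/PD_max + PE/PE_max."""
    if not np.array_equal(pd_surface.cell_ids, pe_surface.cell_ids):
        raise ValueError("PD and PE surfaces are on different cell sets")
    pd_max = float(pd_surface.values.max())
    pe_max = float(pe_surface.values.max())
    if pd_max <= 0 or pe_max <= 0:
        raise ValueError("degenerate landscape: zero PD or PE maximum")
    vals = pd_surface.values / pd_max + pe_surface.values / pe_max
    prov = {"pd_max": pd_max, "pe_max": pe_max}
    return MetricSurface("PA", pd_surface.cell_ids, vals, prov)


# ---------------------------------------------------------------------------
# Pattern correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pattern_correlation(a: MetricSurface, b: MetricSurface) -> CorrelationResult:
    """Pearson r between two surfaces on the same cell set, with the
    two-sided p-value from the t transform."""
    if not np.array_equal(a.cell_ids, b.cell_ids):
        raise ValueError("surfaces are on different cell sets")
    n = len(a.values)
    if n < 3:
        raise ValueError("need at least 3 paired cells")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        raise ValueError("undefined correlation: zero variance")
    res = stats.pearsonr(a.values, b.values)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)
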