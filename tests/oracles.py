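"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: PD/PE
are recomputed per cell by walking the tree, and set cover is solved by
exhaustive subset enumeration.
"""

from itertools import combinations

import dendropy


def brute_pd_pe(newick: str, presence: dict[str, set[int]], cells: list[int]):
    """Per-cell PD and PE by direct spanning-subtree enumeration.

    ``presence`` maps species id -> set of occupied cell ids.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pd_out, pe_out = {}, {}
    for cell in cells:
        spp = {s for s, cs in presence.items() if cell in cs}
        total_pd = 0.0
        total_pe = 0.0
        for node in tree.preorder_node_iter():
            tips = {lf.taxon.label for lf in node.leaf_iter()}
            if tips & spp:
                length = node.edge.length or 0.0
                total_pd += length
                branch_cells = {
                    c
                    for c in cells
                    for s in tips
                    if s in presence and c in presence[s]
                }
                total_pe += length / len(branch_cells)
        pd_out[cell] = total_pd
        pe_out[cell] = total_pe
    return pd_out, pe_out


def brute_min_cover(cell_species: dict[int, set[str]]) -> int:
    """Exhaustive minimum set-cover size (feasible up to ~12 cells)."""
    universe = set().union(*cell_species.values())
    cells = list(cell_species)
    for k in range(1, len(cells) + 1):
        for combo in combinations(cells, k):
            if set().union(*(cell_species[c] for c in combo)) == universe:
                return k
    raise AssertionError("no cover exists")
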