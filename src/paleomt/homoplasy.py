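"""Clade-level homoplasy analysis of a mitogenome alignment.

Pipeline: trim the hypervariable control region (D-loop) out of the
alignment, reconstruct ancestral states on an outgroup-rooted tree by
parsimony, call per-clade *derived* positions (columns whose state at the
clade's MRCA differs from the state at the ingroup root), count *shared*
derived positions between clade pairs (identical derived states acquired
independently rather than inherited — homoplasies), and classify coding
positions as synonymous or non-synonymous under the vertebrate
mitochondrial genetic code.

The small-parsimony step is exact unit-cost dynamic programming (the
Sankoff/Hartigan generalisation of Fitch), valid on multifurcating as well
as binary trees; on binary trees it reduces to classic Fitch.  Top-down
resolution prefers the parent's state; root ambiguity is broken toward the
outgroup's observed state; any remaining arbitrary choice is flagged
ambiguous and excluded from derived counts.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio.Seq import Seq

from .errors import DataError, UsageError
from .io import SequenceRecord, GeneAnnotation, revcomp

_STATE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_STATES = "ACGT"
_INF = np.float64(1e9)

OUTGROUP_LABEL = "outgroup"
DEFAULT_DLOOP = (15422, 16770)  # 1-based inclusive, reference coordinates

MISSING_FRACTION_MAX = 0.5  # columns with more missing data are not counted


# ---------------------------------------------------------------------------
# Alignment helpers
# ---------------------------------------------------------------------------


def _alignment_dict(alignment: Sequence[SequenceRecord]) -> dict[str, str]:
    seqs: dict[str, str] = {}
    length = None
    for rec in alignment:
        if rec.id in seqs:
            raise DataError(f"duplicate sequence label {rec.id!r}")
        if length is None:
            length = len(rec.sequence)
        elif len(rec.sequence) != length:
            raise DataError(
                f"alignment rows differ in length ({rec.id!r}: "
                f"{len(rec.sequence)} vs {length})"
            )
        seqs[rec.id] = rec.sequence
    return seqs


def reference_coordinates(reference_row: str) -> np.ndarray:
    """1-based reference coordinate per alignment column (gap columns get
    the coordinate of the preceding reference base; 0 before the first)."""
    coords = np.cumsum([0 if c == "-" else 1 for c in reference_row])
    return coords


def trim_dloop(
    alignment: Sequence[SequenceRecord],
    interval: tuple[int, int] | None,
    ref_label: str,
) -> list[SequenceRecord]:
    """Remove the alignment columns aligned to a reference interval.

    ``interval`` is 1-based inclusive in the coordinate frame of the row
    named ``ref_label``; ``None`` leaves the alignment unchanged.  Columns
    that are insertions relative to the reference are removed when they
    fall strictly inside the interval.  All rows shrink equally.
    """
    if interval is None:
        return list(alignment)
    start, end = interval
    seqs = _alignment_dict(alignment)
    if ref_label not in seqs:
        raise DataError(f"reference row {ref_label!r} not in alignment")
    ref_row = seqs[ref_label]
    ref_len = sum(1 for c in ref_row if c != "-")
    if not (1 <= start <= end):
        raise UsageError(f"bad interval {start}:{end}")
    if end > ref_len:
        raise DataError(
            f"interval end {end} beyond reference length {ref_len}"
        )
    coords = reference_coordinates(ref_row)
    keep = []
    for col, c in enumerate(ref_row):
        coord = coords[col]
        if c != "-":
            drop = start <= coord <= end
        else:
            drop = start <= coord < end
        if not drop:
            keep.append(col)
    return [
        SequenceRecord(rec.id, "".join(seqs[rec.id][c] for c in keep))
        for rec in alignment
    ]


# ---------------------------------------------------------------------------
# Parsimony ancestral reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AncestralAssignment:
    """Per-column ancestral states on a rooted tree.

    ``states[c, k]`` is the state index (0..3 = A,C,G,T) of node ``k`` (in
    postorder) at column ``c``; ``ambiguous[c, k]`` marks nodes whose state
    was an arbitrary choice among equally parsimonious options.  ``scores``
    holds the minimal number of state changes per column.
    """

    tree: dendropy.Tree
    nodes: list  # postorder dendropy nodes
    node_index: dict  # id(node) -> postorder index
    leaf_labels: list[str]
    n_columns: int
    states: np.ndarray  # (ncols, nnodes) int8
    ambiguous: np.ndarray  # (ncols, nnodes) bool
    scores: np.ndarray  # (ncols,) int
    missing_fraction: np.ndarray  # (ncols,) fraction of missing leaf states

    @property
    def total_score(self) -> int:
        return int(self.scores.sum())

    def node_for(self, labels: Sequence[str]):
        """MRCA node of the given leaf labels."""
        labels = list(labels)
        if len(labels) == 1:
            node = self.tree.find_node_with_taxon_label(labels[0])
            if node is None:
                raise DataError(f"leaf {labels[0]!r} not in tree")
            return node
        taxa = [self.tree.taxon_namespace.get_taxon(l) for l in labels]
        if any(t is None for t in taxa):
            missing = [l for l, t in zip(labels, taxa) if t is None]
            raise DataError(f"leaves not in tree: {missing}")
        return self.tree.mrca(taxa=taxa)

    def node_states(self, node) -> np.ndarray:
        return self.states[:, self.node_index[id(node)]]

    def node_ambiguous(self, node) -> np.ndarray:
        return self.ambiguous[:, self.node_index[id(node)]]

    @property
    def countable(self) -> np.ndarray:
        """Columns with enough data to enter derived/shared counts."""
        return self.missing_fraction <= MISSING_FRACTION_MAX


def fitch(
    tree: dendropy.Tree, alignment: Sequence[SequenceRecord]
) -> AncestralAssignment:
    """Exact small-parsimony ancestral reconstruction over all columns.

    Leaf N or ``-`` is treated as missing (no constraint).  The tree must
    be rooted; the leaf set must equal the alignment's label set.  The
    per-column score equals the minimum possible number of state changes
    (exact also on multifurcating nodes).
    """
    seqs = _alignment_dict(alignment)
    leaf_labels = sorted(seqs)
    tree_labels = sorted(
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon
    )
    if tree_labels != leaf_labels:
        only_tree = sorted(set(tree_labels) - set(leaf_labels))
        only_aln = sorted(set(leaf_labels) - set(tree_labels))
        raise DataError(
            f"tree/alignment leaf mismatch: only in tree {only_tree}, "
            f"only in alignment {only_aln}"
        )
    ncols = len(next(iter(seqs.values())))
    nodes = list(tree.postorder_node_iter())
    node_index = {id(n): i for i, n in enumerate(nodes)}
    nnodes = len(nodes)

    # leaf state matrix: (ncols, nleaves) with -1 for missing
    leaf_state: dict[int, np.ndarray] = {}
    n_missing = np.zeros(ncols)
    nleaves = 0
    for node in nodes:
        if node.is_leaf():
            nleaves += 1
            seq = seqs[node.taxon.label]
            arr = np.array(
                [_STATE_INDEX.get(c, -1) for c in seq], dtype=np.int8
            )
            leaf_state[id(node)] = arr
            n_missing += arr < 0

    # upward: unit-cost DP, cost[c, s] = min changes in subtree given state s
    cost: dict[int, np.ndarray] = {}
    for node in nodes:
        if node.is_leaf():
            arr = leaf_state[id(node)]
            m = np.zeros((ncols, 4))
            observed = arr >= 0
            m[observed] = _INF
            m[observed, arr[observed]] = 0.0
            cost[id(node)] = m
        else:
            children = node.child_nodes()
            total = np.zeros((ncols, 4))
            for ch in children:
                c = cost[id(ch)]
                total += np.minimum(c, c.min(axis=1, keepdims=True) + 1.0)
            cost[id(node)] = total

    root = tree.seed_node
    root_cost = cost[id(root)]
    scores = root_cost.min(axis=1).astype(np.int64)

    # outgroup preference for root ties: state of a leaf child of the root
    out_pref = np.full(ncols, -1, dtype=np.int8)
    for ch in root.child_nodes():
        if ch.is_leaf():
            out_pref = leaf_state[id(ch)].copy()
            break

    states = np.full((ncols, nnodes), -1, dtype=np.int8)
    ambiguous = np.zeros((ncols, nnodes), dtype=bool)
    cols = np.arange(ncols)

    def resolve(node, parent_state: np.ndarray | None) -> None:
        k = node_index[id(node)]
        if node.is_leaf():
            arr = leaf_state[id(node)]
            chosen = np.where(arr >= 0, arr, parent_state if parent_state is not None else 0)
            states[:, k] = chosen
        else:
            c = cost[id(node)]
            if parent_state is None:
                v = c
                pref = out_pref
            else:
                penalty = np.ones((ncols, 4))
                penalty[cols, parent_state] = 0.0
                v = c + penalty
                pref = parent_state
            vmin = v.min(axis=1, keepdims=True)
            is_min = v <= vmin + 1e-9
            nmin = is_min.sum(axis=1)
            first_min = np.argmax(is_min, axis=1).astype(np.int8)
            pref_ok = (pref >= 0) & is_min[cols, np.clip(pref, 0, 3)]
            chosen = np.where(pref_ok, np.clip(pref, 0, 3), first_min)
            states[:, k] = chosen
            ambiguous[:, k] = (nmin > 1) & ~pref_ok
        child_state = states[:, k]
        for ch in node.child_nodes():
            resolve(ch, child_state)

    # dendropy trees can be deep; resolve iteratively to avoid recursion limits
    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * nnodes + 1000))
    try:
        resolve(root, None)
    finally:
        sys.setrecursionlimit(old_limit)

    return AncestralAssignment(
        tree=tree,
        nodes=nodes,
        node_index=node_index,
        leaf_labels=leaf_labels,
        n_columns=ncols,
        states=states,
        ambiguous=ambiguous,
        scores=scores,
        missing_fraction=n_missing / max(nleaves, 1),
    )


# ---------------------------------------------------------------------------
# Derived and shared derived positions
# ---------------------------------------------------------------------------


def _clade_leaves(clade_map: Mapping[str, str], clade: str) -> list[str]:
    leaves = [l for l, c in clade_map.items() if c == clade]
    if not leaves:
        raise DataError(f"clade {clade!r} absent from clade map")
    return leaves


def _ingroup_root(
    assignment: AncestralAssignment, clade_map: Mapping[str, str],
    outgroup_label: str = OUTGROUP_LABEL,
):
    ingroup = [l for l, c in clade_map.items() if c != outgroup_label]
    if not ingroup:
        raise DataError("clade map has no ingroup leaves")
    return assignment.node_for(ingroup)


def derived_positions(
    assignment: AncestralAssignment,
    clade_map: Mapping[str, str],
    clade: str,
    outgroup_label: str = OUTGROUP_LABEL,
) -> dict[int, tuple[str, str]]:
    """Columns derived on the clade's stem branch.

    A column is derived for a clade when the (unambiguous) state at the
    clade's MRCA differs from the (unambiguous) state at the ingroup root
    — the MRCA of all non-outgroup leaves.  Columns with more than 50%
    missing leaf data are excluded.  Returns ``{column: (ancestral,
    derived)}`` with 0-based columns.
    """
    leaves = _clade_leaves(clade_map, clade)
    mrca = assignment.node_for(leaves)
    ing = _ingroup_root(assignment, clade_map, outgroup_label)
    s_clade = assignment.node_states(mrca)
    s_root = assignment.node_states(ing)
    ok = (
        assignment.countable
        & ~assignment.node_ambiguous(mrca)
        & ~assignment.node_ambiguous(ing)
        & (s_clade != s_root)
    )
    return {
        int(c): (_STATES[s_root[c]], _STATES[s_clade[c]])
        for c in np.nonzero(ok)[0]
    }


def shared_derived(
    assignment: AncestralAssignment,
    clade_map: Mapping[str, str],
    clade_a: str,
    clade_b: str,
    outgroup_label: str = OUTGROUP_LABEL,
) -> dict[int, str]:
    """Homoplasic columns shared by two clades.

    Counts columns derived in both clades with the same derived state at
    both MRCAs, excluding columns whose shared state is already present at
    the MRCA of the union (inherited rather than independently acquired).
    Returns ``{column: shared_state}``; symmetric in its clade arguments.
    """
    if clade_a == clade_b:
        raise UsageError("shared_derived requires two distinct clades")
    der_a = derived_positions(assignment, clade_map, clade_a, outgroup_label)
    der_b = derived_positions(assignment, clade_map, clade_b, outgroup_label)
    union_node = assignment.node_for(
        _clade_leaves(clade_map, clade_a) + _clade_leaves(clade_map, clade_b)
    )
    s_union = assignment.node_states(union_node)
    amb_union = assignment.node_ambiguous(union_node)
    shared: dict[int, str] = {}
    for col, (_, state_a) in der_a.items():
        if col not in der_b:
            continue
        if state_a != der_b[col][1]:
            continue
        if not amb_union[col] and _STATES[s_union[col]] == state_a:
            continue  # inherited from the common stem, not homoplasic
        shared[col] = state_a
    return shared


# ---------------------------------------------------------------------------
# Coding-effect classification
# ---------------------------------------------------------------------------


def classify_effect(
    assignment: AncestralAssignment,
    clade_map: Mapping[str, str],
    column: int,
    derived_state: str,
    annotations: Sequence[GeneAnnotation],
    reference_row: SequenceRecord,
    outgroup_label: str = OUTGROUP_LABEL,
) -> str:
    """Synonymous / nonsynonymous / noncoding call for one derived column.

    The codon containing the column is reconstructed from the ingroup-root
    states (reference coordinates via ``reference_row``, the aligned row
    matching the annotation frame).  Reverse-strand genes are complemented
    before translation with the annotation's genetic code (vertebrate
    mitochondrial by default).  Returns ``"unresolved"`` when any codon
    position is missing or ambiguous at the ingroup root.
    """
    ref_row = reference_row.sequence
    coords = reference_coordinates(ref_row)
    if ref_row[column] == "-":
        return "noncoding"  # insertion relative to the annotation frame
    ref_pos = int(coords[column])

    ann = next((a for a in annotations if a.start <= ref_pos <= a.end), None)
    if ann is None:
        return "noncoding"

    # alignment column of each reference position within the codon
    col_of: dict[int, int] = {}
    for c, ch in enumerate(ref_row):
        if ch != "-":
            col_of[int(coords[c])] = c

    if ann.strand == "+":
        offset = (ref_pos - ann.start) % 3
        codon_pos = [ref_pos - offset + k for k in range(3)]
        slot = offset
    else:
        offset = (ann.end - ref_pos) % 3
        codon_pos = [ref_pos + offset - 2 + k for k in range(3)]
        slot = 2 - offset  # slot in reference orientation before complementing

    ing = _ingroup_root(assignment, clade_map, outgroup_label)
    s_root = assignment.node_states(ing)
    amb_root = assignment.node_ambiguous(ing)

    codon = []
    for p in codon_pos:
        if p < ann.start or p > ann.end or p not in col_of:
            return "unresolved"
        c = col_of[p]
        if amb_root[c] or not assignment.countable[c]:
            return "unresolved"
        codon.append(_STATES[s_root[c]])
    anc_codon = "".join(codon)
    der_codon = anc_codon[:slot] + derived_state + anc_codon[slot + 1 :]
    if ann.strand == "-":
        anc_codon = revcomp(anc_codon)
        der_codon = revcomp(der_codon)
    aa_anc = str(Seq(anc_codon).translate(table=ann.genetic_code))
    aa_der = str(Seq(der_codon).translate(table=ann.genetic_code))
    return "synonymous" if aa_anc == aa_der else "nonsynonymous"


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def derived_site_report(
    assignment: AncestralAssignment,
    clade_map: Mapping[str, str],
    annotations: Sequence[GeneAnnotation] | None = None,
    reference_row: SequenceRecord | None = None,
    outgroup_label: str = OUTGROUP_LABEL,
):
    """Tabulate derived and shared derived sites across all clades.

    Returns a pandas DataFrame with one row per column that is derived in
    at least one clade: column (1-based), per-clade derived state (or
    '.'), per-pair shared flags, and the coding effect when annotations
    and a reference row are supplied.
    """
    import pandas as pd

    clades = sorted({c for c in clade_map.values() if c != outgroup_label})
    derived = {
        c: derived_positions(assignment, clade_map, c, outgroup_label)
        for c in clades
    }
    pairs = [
        (a, b) for i, a in enumerate(clades) for b in clades[i + 1 :]
    ]
    shared = {
        (a, b): shared_derived(assignment, clade_map, a, b, outgroup_label)
        for a, b in pairs
    }
    all_cols = sorted(set().union(*[d.keys() for d in derived.values()]))
    rows = []
    for col in all_cols:
        row: dict = {"column": col + 1}
        der_state = None
        for c in clades:
            if col in derived[c]:
                row[f"derived_{c}"] = derived[c][col][1]
                der_state = derived[c][col][1]
            else:
                row[f"derived_{c}"] = "."
        for a, b in pairs:
            row[f"shared_{a}_{b}"] = col in shared[(a, b)]
        if annotations is not None and reference_row is not None and der_state:
            row["effect"] = classify_effect(
                assignment, clade_map, col, der_state, annotations,
                reference_row, outgroup_label,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Neighbour joining (test-scale tree building)
# ---------------------------------------------------------------------------


def p_distance_matrix(alignment: Sequence[SequenceRecord]) -> tuple[np.ndarray, list[str]]:
    """Uncorrected pairwise p-distances (sites with both bases in ACGT)."""
    seqs = _alignment_dict(alignment)
    labels = sorted(seqs)
    mats = np.array(
        [[_STATE_INDEX.get(c, -1) for c in seqs[l]] for l in labels], dtype=np.int8
    )
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (mats[i] >= 0) & (mats[j] >= 0)
            comparable = int(both.sum())
            if comparable == 0:
                d = 0.0
            else:
                d = float(((mats[i] != mats[j]) & both).sum()) / comparable
            dist[i, j] = dist[j, i] = d
    return dist, labels


def nj_tree(
    alignment: Sequence[SequenceRecord], outgroup: str | None = None
) -> dendropy.Tree:
    """Neighbour-joining tree on p-distances (deterministic, label-sorted).

    Intended for test-scale trees; production trees should come from a
    dedicated phylogenetics tool and be supplied as newick input.  When
    ``outgroup`` is given the tree is rooted on that leaf's edge.
    """
    if len(alignment) < 3:
        raise UsageError("nj_tree needs at least 3 sequences")
    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    dist, labels = p_distance_matrix(alignment)
    sk_tree = _skbio_nj(DistanceMatrix(dist, ids=labels))
    newick = _io.StringIO()
    sk_tree.write(newick, format="newick")
    tree = dendropy.Tree.get(
        data=newick.getvalue(), schema="newick", preserve_underscores=True
    )
    if outgroup is not None:
        tree = root_on_outgroup(tree, outgroup)
    return tree


def root_on_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Reroot so the outgroup leaf is a direct child of the root."""
    node = tree.find_node_with_taxon_label(outgroup_label)
    if node is None:
        raise DataError(f"outgroup {outgroup_label!r} not in tree")
    if node.edge.length is None:
        node.edge.length = 1.0
    tree.reroot_at_edge(node.edge, update_bipartitions=True)
    tree.is_rooted = True
    return tree
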