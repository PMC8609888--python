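"""Alignment post-processing, NJ tree building, rooting and clade assignment.

Alignment columns are 1-based throughout. Trees are handled as
:class:`dendropy.Tree` objects; internal node labels are interpreted as
bootstrap-style support values on the 0–100 scale, with unlabeled nodes
treated as fully supported (``default_support``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import median_low
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from tollscan.domain_scan import Architecture

GAP = "-"

CLADE_LABELS = ("alpha", "beta", "gamma")
UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# alignment container

@dataclass(frozen=True)
class Alignment:
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        ids = [sid for sid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for sid, seq in self.rows:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def take_columns(self, cols0: Sequence[int]) -> "Alignment":
        """New alignment keeping 0-based columns ``cols0`` in the given order."""
        return Alignment(tuple(
            (sid, "".join(seq[c] for c in cols0)) for sid, seq in self.rows
        ))

    def gap_fractions(self) -> np.ndarray:
        mat = np.array([list(seq) for _, seq in self.rows])
        return (mat == GAP).mean(axis=0)


def read_alignment(path: str | Path) -> Alignment:
    rows, cur_id, cur = [], None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if cur_id is not None:
                    rows.append((cur_id, "".join(cur)))
                cur_id = line[1:].split()[0]
                cur = []
            elif line:
                cur.append(line)
    if cur_id is not None:
        rows.append((cur_id, "".join(cur)))
    return Alignment(tuple(rows))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.rows:
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# trimming / masking

def extract_core_columns(
    aln: Alignment,
    archs: Mapping[str, Architecture],
) -> Alignment:
    """Keep the contiguous block from the membrane-proximal LRR to the TIR end.

    A deterministic surrogate for a manual core trim: the start column is the
    median (across rows) column holding the start of the last LRR unit before
    the TM, the end column is the median column holding the last TIR residue.
    """
    start_cols, end_cols = [], []
    for sid, seq in aln.rows:
        if sid not in archs:
            raise ValueError(f"no architecture for aligned sequence {sid!r}")
        arch = archs[sid]
        if arch.tm is None or arch.tir is None:
            raise ValueError(f"{sid}: architecture lacks TM or TIR")
        lrrs = [h for h in arch.hits_of("LRR") if h.start < arch.tm.start]
        if not lrrs:
            raise ValueError(f"{sid}: no LRR N-terminal of the TM")
        proximal = max(lrrs, key=lambda h: h.start)
        col_of = [i for i, c in enumerate(seq) if c != GAP]  # residue idx -> col0
        start_cols.append(col_of[proximal.start - 1])
        end_cols.append(col_of[arch.tir.end - 1])
    start0 = median_low(start_cols)
    end0 = median_low(end_cols)
    return aln.take_columns(range(start0, end0 + 1))


def gappyout_cutoff(gap_fractions: Sequence[float]) -> float:
    """Automatic gap-fraction cutoff at the steepest break of the sorted curve.

    The cutoff is the value just below the largest jump between consecutive
    sorted gap fractions (first such jump on ties); columns with a strictly
    larger gap fraction are removed. When all fractions are equal there is no
    break and nothing is trimmed.
    """
    ordered = sorted(gap_fractions)
    best_jump, cutoff = 0.0, ordered[-1]
    for a, b in zip(ordered, ordered[1:]):
        if b - a > best_jump:
            best_jump, cutoff = b - a, a
    return cutoff


def trim_gappyout(aln: Alignment) -> Alignment:
    if aln.n_cols < 3:
        raise ValueError("gappyout requires at least 3 columns")
    fracs = aln.gap_fractions()
    if np.all(fracs >= 1.0):
        raise ValueError("degenerate alignment: every column is fully gapped")
    cutoff = gappyout_cutoff(fracs)
    keep = [i for i, f in enumerate(fracs) if f <= cutoff]
    if not keep:
        raise ValueError("gappyout removed every column")
    return aln.take_columns(keep)


def mask_region(aln: Alignment, start: int, end: int) -> Alignment:
    """Remove 1-based columns ``start..end`` inclusive."""
    if not (1 <= start <= end <= aln.n_cols):
        raise ValueError(f"mask range {start}..{end} outside 1..{aln.n_cols}")
    keep = [i for i in range(aln.n_cols) if not (start - 1 <= i <= end - 1)]
    return aln.take_columns(keep)


def detect_insertion(
    aln: Alignment,
    start: int,
    end: int,
    min_nongap: int = 5,
) -> dict[str, bool]:
    """Row carries the insertion iff >= ``min_nongap`` residues fill the window."""
    if not (1 <= start <= end <= aln.n_cols):
        raise ValueError(f"window {start}..{end} outside 1..{aln.n_cols}")
    out = {}
    for sid, seq in aln.rows:
        window = seq[start - 1:end]
        out[sid] = sum(1 for c in window if c != GAP) >= min_nongap
    return out


# ---------------------------------------------------------------------------
# distances and neighbor joining

def p_distance_matrix(aln: Alignment) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances ignoring columns gapped in either sequence."""
    ids = aln.ids
    mat = np.array([list(seq) for _, seq in aln.rows])
    gaps = mat == GAP
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gaps[i] & ~gaps[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(f"no shared ungapped columns for {ids[i]}/{ids[j]}")
            mism = int((mat[i, shared] != mat[j, shared]).sum())
            d[i, j] = d[j, i] = mism / total
    return ids, d


def nj_tree_from_distances(ids: Sequence[str], d: np.ndarray) -> dendropy.Tree:
    """Classic neighbor joining with deterministic lexicographic tie-breaking."""
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in ids:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label=name)
        nodes.append(node)
    dm = d.astype(float).copy()

    def join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        parent = dendropy.Node()
        ci, cj = nodes[i_pos], nodes[j_pos]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = max(0.0, li)
        cj.edge.length = max(0.0, lj)
        nodes[i_pos] = parent
        del nodes[j_pos]

    while len(nodes) > 2:
        m = len(nodes)
        r = dm.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = dm[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        new_row = np.array([
            0.0 if k == i else (dm[i, k] + dm[j, k] - dij) / 2
            for k in range(m)
        ])
        dm[i, :] = new_row
        dm[:, i] = new_row
        dm = np.delete(np.delete(dm, j, axis=0), j, axis=1)
        join(i, j, li, lj)

    root = dendropy.Node()
    if len(nodes) == 2:
        a, b = nodes
        root.add_child(a)
        root.add_child(b)
        a.edge.length = max(0.0, dm[0, 1] / 2)
        b.edge.length = max(0.0, dm[0, 1] / 2)
    else:
        for node in nodes:
            root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def build_nj_tree(aln: Alignment) -> dendropy.Tree:
    if len(aln.rows) < 3:
        raise ValueError("need at least 3 rows for a tree")
    ids, d = p_distance_matrix(aln)
    return nj_tree_from_distances(ids, d)


# ---------------------------------------------------------------------------
# tree helpers

def read_tree(source: str | Path, *, is_path: bool | None = None) -> dendropy.Tree:
    """Read a newick tree; internal labels are kept as plain node labels."""
    text = None
    if is_path is None:
        is_path = isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                               and "(" not in source)
    if is_path:
        text = Path(source).read_text()
    else:
        text = str(source)
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def node_support(node: dendropy.Node, default: float = 100.0) -> float:
    if node.label is None or node.label == "":
        return default
    try:
        return float(node.label)
    except ValueError:
        return default


def root_with_outgroup(tree: dendropy.Tree, outgroup_tips: Iterable[str]) -> dendropy.Tree:
    """Root on the edge separating a monophyletic outgroup from the ingroup."""
    outgroup = frozenset(outgroup_tips)
    tree = tree.clone(depth=1)
    all_tips = leaf_labels(tree.seed_node)
    missing = outgroup - all_tips
    if missing:
        raise ValueError(f"outgroup tips not in tree: {sorted(missing)}")
    target = None
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = leaf_labels(node)
        if below == outgroup or below == all_tips - outgroup:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup not monophyletic in the unrooted tree: {sorted(outgroup)}"
        )
    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2, length2=length / 2)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# clade assignment

@dataclass(frozen=True)
class CladeAssignment:
    labels: dict[str, str]  # tip -> alpha | beta | gamma | unassigned

    def members(self, label: str) -> set[str]:
        return {tip for tip, lab in self.labels.items() if lab == label}

    @property
    def counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in (*CLADE_LABELS, UNASSIGNED)}
        for lab in self.labels.values():
            out.setdefault(lab, 0)
            out[lab] += 1
        return out


def assign_clades(
    tree: dendropy.Tree,
    anchors: Mapping[str, Iterable[str]],
    support_min: float = 60.0,
    outgroup_tips: Iterable[str] = (),
    default_support: float = 100.0,
) -> CladeAssignment:
    """Label tips by anchored, support-thresholded clades.

    For each label, the assigned clade is the largest node with support
    strictly above ``support_min`` whose leaf set contains all of the label's
    anchors and none of any other label's anchors. Anchor tips always carry
    their own label; every other tip outside all chosen clades is
    ``unassigned``. Outgroup tips are excluded from the assignment.
    """
    outgroup = frozenset(outgroup_tips)
    anchor_sets = {lab: frozenset(tips) for lab, tips in anchors.items()}
    for lab, tips in anchor_sets.items():
        if tips & outgroup:
            raise ValueError(f"anchors for {lab} overlap the outgroup")
        if not tips:
            raise ValueError(f"empty anchor set for {lab}")
    all_tips = leaf_labels(tree.seed_node) - outgroup
    for lab, tips in anchor_sets.items():
        missing = tips - all_tips
        if missing:
            raise ValueError(f"anchor tips for {lab} not in tree: {sorted(missing)}")

    # two labels whose anchors resolve to the same minimal clade cannot both
    # be honoured by any clade choice
    nodes = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    node_leaves = {id(n): leaf_labels(n) - outgroup for n in nodes}
    minimal_of = {}
    for lab, tips in anchor_sets.items():
        minimal = min(
            (n for n in nodes if tips <= node_leaves[id(n)]),
            key=lambda n: len(node_leaves[id(n)]),
        )
        minimal_of[lab] = id(minimal)
    for lab, tips in anchor_sets.items():
        for other in anchor_sets:
            if other > lab and minimal_of[lab] == minimal_of[other]:
                raise ValueError(
                    f"anchors for {lab!r} and {other!r} resolve to the same "
                    "minimal clade; anchors inconsistent with tree"
                )

    labels = {tip: UNASSIGNED for tip in all_tips}
    for lab, tips in anchor_sets.items():
        others = frozenset().union(
            *(t for other, t in anchor_sets.items() if other != lab)
        )
        candidates = [
            n for n in nodes
            if tips <= node_leaves[id(n)]
            and not (others & node_leaves[id(n)])
            and node_support(n, default=default_support) > support_min
        ]
        chosen = max(candidates, key=lambda n: len(node_leaves[id(n)]), default=None)
        member_tips = node_leaves[id(chosen)] if chosen is not None else tips
        for tip in member_tips | tips:
            labels[tip] = lab
    return CladeAssignment(labels=labels)
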