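"""Dollo gain/loss reconstruction and origin-hypothesis ranking.

Characters (``Calpha``, ``Cbeta``, ``Cgamma``) evolve on a fixed, named
metazoan species tree under a single-gain / multiple-loss (Dollo) model.
The packaged fixture tree and presence matrix follow the study design:
leaves are metazoan groups, internal nodes carry lineage names
(Planulozoa, Nephrozoa, Protostomia, Spiralia, Trochozoa, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from tollscan.phylo import CladeAssignment, leaf_labels, read_tree
from tollscan.receptor_survey import SurveyResult

CHARACTERS = ("Calpha", "Cbeta", "Cgamma")

HYPOTHESIS_IDS = ("1A", "1B", "2A", "2B", "2C")


def load_species_tree() -> dendropy.Tree:
    """The packaged metazoan species-tree fixture with named internal nodes."""
    text = resources.files("tollscan.data").joinpath("species_tree.nwk").read_text()
    tree = read_tree(text, is_path=False)
    tree.is_rooted = True
    return tree


def load_presence_fixture() -> pd.DataFrame:
    """The packaged group-level clade presence/absence matrix."""
    with resources.files("tollscan.data").joinpath("clade_presence.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="taxon")
    return df.astype(bool)


def _named_node(tree: dendropy.Tree, name: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        label = node.label or (node.taxon.label if node.taxon else None)
        if label == name:
            return node
    raise KeyError(f"no node named {name!r} in species tree")


# ---------------------------------------------------------------------------
# presence matrix

def build_presence_matrix(
    assignments: Mapping[str, CladeAssignment],
    surveys: Mapping[str, SurveyResult],
    tree: dendropy.Tree | None = None,
    tip_to_species: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """taxon x character boolean table from per-species clade assignments.

    ``assignments`` maps species/taxon name to the clade labels of that
    species' TLR tips (tips are mapped to species via ``tip_to_species``
    when given, else by exact name). Species with a survey entry but no
    labeled tips get an all-false row.
    """
    if tree is None:
        tree = load_species_tree()
    taxa = leaf_labels(tree.seed_node)
    clade_to_char = {"alpha": "Calpha", "beta": "Cbeta", "gamma": "Cgamma"}

    rows: dict[str, dict[str, bool]] = {}
    for species in set(assignments) | set(surveys):
        if species not in taxa:
            raise ValueError(f"species {species!r} absent from the species tree")
        rows[species] = {c: False for c in CHARACTERS}
    for species, assignment in assignments.items():
        for tip, label in assignment.labels.items():
            if tip_to_species is not None and tip_to_species.get(tip, species) != species:
                continue
            if label in clade_to_char:
                rows[species][clade_to_char[label]] = True
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(CHARACTERS))
    return df.sort_index()


# ---------------------------------------------------------------------------
# Dollo reconstruction

@dataclass(frozen=True)
class EventMap:
    character: str
    gain_node: str
    loss_edges: tuple[str, ...]  # named by the child node below each lost edge

    @property
    def total_events(self) -> int:
        return 1 + len(self.loss_edges)


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    # stable surrogate for unnamed internal nodes
    return "{" + "+".join(sorted(leaf_labels(node))) + "}"


def _mrca(tree: dendropy.Tree, tips: frozenset[str]) -> dendropy.Node:
    best = None
    for node in tree.postorder_node_iter():
        if tips <= leaf_labels(node):
            if best is None or len(leaf_labels(node)) < len(leaf_labels(best)):
                best = node
    assert best is not None
    return best


def _min_losses_below(node: dendropy.Node, present: frozenset[str]) -> list[dendropy.Node]:
    """Maximal all-absent subtrees below ``node``: the minimal Dollo loss set."""
    losses: list[dendropy.Node] = []

    def descend(n: dendropy.Node) -> None:
        for child in n.child_nodes():
            if leaf_labels(child) & present:
                descend(child)
            else:
                losses.append(child)

    if not (leaf_labels(node) & present):
        return [node]
    descend(node)
    return losses


def dollo_reconstruct(
    tree: dendropy.Tree,
    character_column: Mapping[str, bool],
    character: str = "",
    gain_node: str | None = None,
) -> EventMap:
    """Single gain at the presence MRCA (or a constrained ancestor) plus the
    minimal set of loss edges explaining every absent leaf."""
    present = frozenset(t for t, state in character_column.items() if state)
    if not present:
        raise ValueError("all-absent character: nothing to reconstruct")
    if gain_node is None:
        gain = _mrca(tree, present)
    else:
        gain = _named_node(tree, gain_node)
        if not (present <= leaf_labels(gain)):
            raise ValueError(
                f"gain node {gain_node!r} not ancestral to all presence taxa"
            )
    # leaves outside the gain subtree are absent by construction; only leaves
    # below the gain can require losses
    losses = _min_losses_below(gain, present)
    return EventMap(
        character=character,
        gain_node=_node_name(gain),
        loss_edges=tuple(sorted(_node_name(n) for n in losses)),
    )


def score_gain_placement(
    tree: dendropy.Tree,
    character_column: Mapping[str, bool],
    gain_node: str,
) -> int:
    """Minimal implied loss count for a forced gain placement."""
    event_map = dollo_reconstruct(tree, character_column, gain_node=gain_node)
    return len(event_map.loss_edges)


# ---------------------------------------------------------------------------
# hypotheses

@dataclass(frozen=True)
class Hypothesis:
    id: str
    description: str
    gains: tuple[tuple[str, str], ...]  # (character, gain node)
    implied_losses: int
    gene_tree_consistent: bool
    feasible: bool = True  # False when a constrained gain cannot cover the data

    @property
    def total_events(self) -> int:
        return len(self.gains) + self.implied_losses


def _column(matrix: pd.DataFrame, char: str) -> dict[str, bool]:
    return {taxon: bool(v) for taxon, v in matrix[char].items()}


def _merged_beta_gamma(matrix: pd.DataFrame) -> dict[str, bool]:
    return {
        taxon: bool(matrix.at[taxon, "Cbeta"] or matrix.at[taxon, "Cgamma"])
        for taxon in matrix.index
    }


def gene_tree_signals(
    assignment: CladeAssignment,
    cnidarian_tips: Iterable[str],
) -> tuple[bool, bool]:
    """(cnidarians nested within clade alpha, gamma clade not nested in beta).

    The first signal discriminates the single- vs two-gene planulozoan
    ancestor hypotheses; the second discriminates a pre-split beta/gamma
    duplication from a duplication inside the beta diversification.
    """
    cnidarian = set(cnidarian_tips)
    alpha = assignment.members("alpha")
    beta = assignment.members("beta")
    gamma = assignment.members("gamma")
    cnidarians_in_alpha = bool(cnidarian) and cnidarian <= alpha and bool(alpha - cnidarian)
    gamma_outside_beta = bool(gamma) and not (gamma & beta)
    return cnidarians_in_alpha, gamma_outside_beta


def rank_hypotheses(
    matrix: pd.DataFrame,
    tree: dendropy.Tree,
    assignment: CladeAssignment,
    cnidarian_tips: Iterable[str],
) -> list[Hypothesis]:
    """Enumerate the five origin hypotheses, score each by implied events and
    flag gene-tree consistency; order consistent-first, then fewest events.

    1A/1B place the alpha vs beta/gamma split after/before the cnidarian
    divergence; 2A/2B/2C place the beta vs gamma duplication at Nephrozoa,
    Spiralia or Trochozoa.
    """
    cnid_in_alpha, gamma_outside_beta = gene_tree_signals(assignment, cnidarian_tips)
    alpha_col = _column(matrix, "Calpha")
    beta_col = _column(matrix, "Cbeta")
    gamma_col = _column(matrix, "Cgamma")
    bg_col = _merged_beta_gamma(matrix)

    alpha_losses = score_gain_placement(tree, alpha_col, "Planulozoa")

    hypotheses = []
    # family 1: content of the planulozoan ancestor
    for hid, bg_gain, consistent, desc in [
        ("1A", "Nephrozoa", not cnid_in_alpha,
         "one TLR in the planulozoan ancestor; beta/gamma precursor arises in Nephrozoa"),
        ("1B", "Planulozoa", cnid_in_alpha,
         "two TLRs in the planulozoan ancestor; beta/gamma precursor lost in cnidarians"),
    ]:
        losses = alpha_losses + score_gain_placement(tree, bg_col, bg_gain)
        hypotheses.append(Hypothesis(
            id=hid,
            description=desc,
            gains=(("Calpha", "Planulozoa"), ("Cbeta/gamma", bg_gain)),
            implied_losses=losses,
            gene_tree_consistent=consistent,
        ))
    # family 2: where beta/gamma duplicated
    for hid, gamma_gain, consistent, desc in [
        ("2A", "Nephrozoa", gamma_outside_beta,
         "beta/gamma duplication in the nephrozoan ancestor"),
        ("2B", "Spiralia", not gamma_outside_beta,
         "beta/gamma duplication in the spiralian ancestor"),
        ("2C", "Trochozoa", not gamma_outside_beta,
         "beta/gamma duplication in the trochozoan ancestor"),
    ]:
        feasible = True
        try:
            losses = (
                alpha_losses
                + score_gain_placement(tree, beta_col, "Nephrozoa")
                + score_gain_placement(tree, gamma_col, gamma_gain)
            )
        except ValueError:
            # the constrained gain cannot cover the observed presences
            feasible, losses = False, 0
        hypotheses.append(Hypothesis(
            id=hid,
            description=desc,
            gains=(("Calpha", "Planulozoa"), ("Cbeta", "Nephrozoa"),
                   ("Cgamma", gamma_gain)),
            implied_losses=losses,
            gene_tree_consistent=consistent,
            feasible=feasible,
        ))

    hypotheses.sort(key=lambda h: (
        not (h.feasible and h.gene_tree_consistent),
        not h.feasible,
        h.total_events,
        h.id,
    ))
    return hypotheses


# ---------------------------------------------------------------------------
# text rendering

def render_events(tree: dendropy.Tree, events: Sequence[EventMap]) -> str:
    """ASCII rendering of gains (+) and losses (x) on the species tree."""
    gains: dict[str, list[str]] = {}
    losses: dict[str, list[str]] = {}
    for ev in events:
        gains.setdefault(ev.gain_node, []).append(ev.character)
        for edge in ev.loss_edges:
            losses.setdefault(edge, []).append(ev.character)

    lines = []

    def walk(node: dendropy.Node, depth: int) -> None:
        name = _node_name(node)
        marks = []
        if name in gains:
            marks.append("+" + ",".join(sorted(gains[name])))
        if name in losses:
            marks.append("x" + ",".join(sorted(losses[name])))
        suffix = f"  [{' '.join(marks)}]" if marks else ""
        lines.append("  " * depth + name + suffix)
        for child in node.child_nodes():
            walk(child, depth + 1)

    walk(tree.seed_node, 0)
    return "\n".join(lines)
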