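"""TLR / TLR-like calling, per-species redundancy collapse and survey counts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from tollscan.domain_scan import Architecture, annotate_architecture
from tollscan.receptor_typing import classify_type
from tollscan.records import SequenceRecord

CATEGORIES = ("TLR", "TIR_ONLY", "LRR_ONLY", "TIR_LRR_NO_TM", "NONE")


@dataclass(frozen=True)
class ReceptorCall:
    seq_id: str
    category: str


@dataclass(frozen=True)
class SurveyResult:
    species: str
    n_tlr: int
    n_scc: int
    n_mcc: int
    n_nc: int
    tlr_ids: tuple[str, ...]


def call_receptor(arch: Architecture) -> ReceptorCall:
    """TLR iff TIR + TM + >=1 LRR are all present; otherwise a TLR-like bin."""
    if arch.has_tir and arch.has_tm and arch.n_lrr >= 1:
        category = "TLR"
    elif arch.has_tir and arch.n_lrr >= 1:
        category = "TIR_LRR_NO_TM"
    elif arch.has_tir:
        category = "TIR_ONLY"
    elif arch.n_lrr >= 1:
        category = "LRR_ONLY"
    else:
        category = "NONE"
    return ReceptorCall(seq_id=arch.seq_id, category=category)


# ---------------------------------------------------------------------------
# similarity and collapse

# Similarity metric: maximal number of identically aligned residue pairs over
# any global alignment (match 1, mismatch 0, no gap cost -- equivalently the
# longest common subsequence), divided by the shorter sequence length. This
# containment-style score treats a truncated isoform of a sequence as 100%
# similar to it.
_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=0.0,
    extend_gap_score=0.0,
)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    if len(a.residues) == 0 or len(b.residues) == 0:
        raise ValueError("cannot align empty sequences")
    matches = _ALIGNER.score(a.residues, b.residues)
    return float(matches) / min(len(a.residues), len(b.residues))


@dataclass(frozen=True)
class Cluster:
    species: str
    representative: str
    members: tuple[str, ...]


def collapse_redundant(
    records: Sequence[SequenceRecord],
    threshold: float = 0.90,
) -> tuple[list[SequenceRecord], list[Cluster]]:
    """Collapse same-species sequences with identity strictly above ``threshold``.

    Single-linkage components of the identity graph are reduced to one
    representative each: the longest member, ties broken by lexicographically
    smallest id. Cross-species pairs are never compared.
    """
    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)

    kept_ids: set[str] = set()
    clusters: list[Cluster] = []
    for species in sorted(by_species):
        group = by_species[species]
        parent = {r.id: r.id for r in group}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if pairwise_identity(a, b) > threshold:
                    parent[find(a.id)] = find(b.id)

        components: dict[str, list[SequenceRecord]] = {}
        for rec in group:
            components.setdefault(find(rec.id), []).append(rec)
        for comp in components.values():
            rep = min(comp, key=lambda r: (-len(r.residues), r.id))
            kept_ids.add(rep.id)
            clusters.append(Cluster(
                species=species,
                representative=rep.id,
                members=tuple(sorted(r.id for r in comp)),
            ))

    kept = [r for r in records if r.id in kept_ids]
    clusters.sort(key=lambda c: (c.species, c.representative))
    return kept, clusters


# ---------------------------------------------------------------------------
# survey

def survey_proteome(
    records: Sequence[SequenceRecord],
    identity_threshold: float = 0.90,
    archs: dict[str, Architecture] | None = None,
) -> list[SurveyResult]:
    """Annotate, call, collapse and count TLRs per species (Table-1 style).

    Pre-computed architectures may be supplied keyed by sequence id;
    otherwise every record is annotated here.
    """
    if archs is None:
        archs = {r.id: annotate_architecture(r) for r in records}
    calls = {r.id: call_receptor(archs[r.id]) for r in records}
    tlr_records = [r for r in records if calls[r.id].category == "TLR"]
    kept, _ = collapse_redundant(tlr_records, threshold=identity_threshold)

    by_species: dict[str, list[SequenceRecord]] = {}
    for rec in kept:
        by_species.setdefault(rec.species, []).append(rec)

    results = []
    for species in sorted(by_species):
        members = sorted(by_species[species], key=lambda r: r.id)
        types = [classify_type(archs[r.id]).tlr_type for r in members]
        results.append(SurveyResult(
            species=species,
            n_tlr=len(members),
            n_scc=types.count("scc"),
            n_mcc=types.count("mcc"),
            n_nc=types.count("NC"),
            tlr_ids=tuple(r.id for r in members),
        ))
    return results
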