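"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator returns ``(object, truth)`` where ``truth`` is a plain,
JSON-serialisable dict recording the planted facts (domain coordinates,
receptor types, cluster membership, gain/loss events, insertion carriers,
expression classes) together with the seed, sufficient to score pipeline
output without recomputation.

Determinism: all randomness flows through ``numpy.random.default_rng(seed)``.
Noise substitutions never introduce cysteines, so planted cap patterns stay
well-defined.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from tollscan.domain_scan import LRR_CONSENSUS_UNIT, TIR_CONSENSUS
from tollscan.expression import CountMatrix
from tollscan.phylo import Alignment, leaf_labels
from tollscan.records import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
# plausible proteome composition
BACKGROUND_FREQ = {
    "A": 0.08, "C": 0.015, "D": 0.055, "E": 0.065, "F": 0.04, "G": 0.07,
    "H": 0.022, "I": 0.055, "K": 0.06, "L": 0.095, "M": 0.024, "N": 0.042,
    "P": 0.047, "Q": 0.04, "R": 0.052, "S": 0.066, "T": 0.055, "V": 0.068,
    "W": 0.011, "Y": 0.033,
}

_BG_AA = np.array(list(BACKGROUND_FREQ))
_BG_P = np.array(list(BACKGROUND_FREQ.values()))
_BG_P /= _BG_P.sum()
_NOC_MASK = _BG_AA != "C"
_BG_AA_NOC = _BG_AA[_NOC_MASK]
_BG_P_NOC = _BG_P[_NOC_MASK] / _BG_P[_NOC_MASK].sum()

_TM_AA = np.array(list("LIVFA"))
_TM_P = np.array([0.40, 0.20, 0.20, 0.10, 0.10])
TM_LENGTH = 23


def _bg(rng: np.random.Generator, n: int, allow_c: bool = True) -> str:
    if allow_c:
        return "".join(rng.choice(_BG_AA, size=n, p=_BG_P))
    return "".join(rng.choice(_BG_AA_NOC, size=n, p=_BG_P_NOC))


def _noisy(rng: np.random.Generator, segment: str, noise: float) -> str:
    if noise <= 0:
        return segment
    out = list(segment)
    for i in range(len(out)):
        if out[i] != "C" and rng.random() < noise:
            out[i] = str(rng.choice(_BG_AA_NOC, p=_BG_P_NOC))
    return "".join(out)


def _cap(rng: np.random.Generator) -> str:
    """A four-cysteine cluster C-x(2..6)-C-x(8..16)-C-x(4..10)-C."""
    s1, s2, s3 = rng.integers(2, 7), rng.integers(8, 17), rng.integers(4, 11)
    return ("C" + _bg(rng, int(s1), allow_c=False)
            + "C" + _bg(rng, int(s2), allow_c=False)
            + "C" + _bg(rng, int(s3), allow_c=False) + "C")


def save_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# receptors and proteomes

def make_tlr_sequence(
    tlr_type: str,
    n_lrr: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: float = 0.0,
    seq_id: str = "tlr",
    species: str = "synthetic",
    unit_len: int | None = None,
) -> tuple[SequenceRecord, dict]:
    """One planted TLR: LRR array(s), cap(s), TM segment and TIR domain.

    ``scc`` receptors carry a single LRR array followed by one
    membrane-proximal LRRCT; ``mcc`` receptors carry 2–3 arrays each closed
    by an LRRCT (requires ``n_lrr >= 2``) and an LRRNT with probability 0.7.
    """
    if tlr_type not in ("scc", "mcc"):
        raise ValueError(f"invalid TLR type {tlr_type!r}")
    if n_lrr < 1:
        raise ValueError("n_lrr must be >= 1")
    if tlr_type == "mcc" and n_lrr < 2:
        raise ValueError("mcc layout needs at least 2 LRR units")
    if rng is None:
        rng = np.random.default_rng(seed)
    if unit_len is None:
        unit_len = int(rng.integers(22, 27))
    unit = (LRR_CONSENSUS_UNIT * 2)[:unit_len]

    parts: list[str] = []
    hits: list[dict] = []
    pos = 0  # 0-based length so far

    def emit(segment: str, kind: str | None = None) -> None:
        nonlocal pos
        if kind is not None:
            hits.append({"kind": kind, "start": pos + 1, "end": pos + len(segment)})
        parts.append(segment)
        pos += len(segment)

    emit(_bg(rng, int(rng.integers(15, 31)), allow_c=False))

    if tlr_type == "scc":
        array_sizes = [n_lrr]
        has_lrrnt = False
    else:
        k = 2 if n_lrr < 3 else int(rng.integers(2, 4))
        cuts = sorted(rng.choice(np.arange(1, n_lrr), size=k - 1, replace=False))
        array_sizes = [b - a for a, b in zip([0, *cuts], [*cuts, n_lrr])]
        has_lrrnt = bool(rng.random() < 0.7)

    if has_lrrnt:
        emit(_cap(rng), kind="LRRNT")
        emit(_bg(rng, int(rng.integers(2, 8)), allow_c=False))

    for a_idx, size in enumerate(array_sizes):
        for _ in range(size):
            emit(_noisy(rng, unit, noise), kind="LRR")
        emit(_bg(rng, int(rng.integers(3, 11)), allow_c=False))
        if tlr_type == "mcc" or a_idx == len(array_sizes) - 1:
            emit(_cap(rng), kind="LRRCT")
            if a_idx < len(array_sizes) - 1:
                emit(_bg(rng, int(rng.integers(2, 8)), allow_c=False))

    # juxtamembrane charged anchors delimit the TM segment sharply
    emit(_bg(rng, int(rng.integers(5, 19)), allow_c=False) + "RK")
    tm = "".join(rng.choice(_TM_AA, size=TM_LENGTH, p=_TM_P))
    emit(tm, kind="TM")
    emit("KR" + _bg(rng, int(rng.integers(20, 41)), allow_c=False))
    emit(_noisy(rng, TIR_CONSENSUS, noise), kind="TIR")
    emit(_bg(rng, int(rng.integers(10, 21)), allow_c=False))

    record = SequenceRecord(id=seq_id, residues="".join(parts), species=species)
    truth = {
        "seed": seed,
        "seq_id": seq_id,
        "tlr_type": tlr_type,
        "n_lrr": n_lrr,
        "n_lrrct": sum(1 for h in hits if h["kind"] == "LRRCT"),
        "has_lrrnt": has_lrrnt,
        "unit_len": unit_len,
        "hits": hits,
    }
    return record, truth


def _mutate(
    rng: np.random.Generator,
    residues: str,
    n_subs: int,
) -> str:
    """Substitute ``n_subs`` non-cysteine positions with different residues."""
    out = list(residues)
    eligible = [i for i, c in enumerate(out) if c != "C"]
    chosen = rng.choice(np.array(eligible), size=min(n_subs, len(eligible)), replace=False)
    for i in chosen:
        current = out[int(i)]
        replacement = current
        while replacement == current:
            replacement = str(rng.choice(_BG_AA_NOC, p=_BG_P_NOC))
        out[int(i)] = replacement
    return "".join(out)


def make_tir_only(rng: np.random.Generator, seq_id: str, species: str,
                  noise: float = 0.0) -> tuple[SequenceRecord, dict]:
    leader = _bg(rng, int(rng.integers(20, 60)))
    tir = _noisy(rng, TIR_CONSENSUS, noise)
    tail = _bg(rng, int(rng.integers(10, 40)))
    rec = SequenceRecord(id=seq_id, residues=leader + tir + tail, species=species)
    truth = {"seq_id": seq_id, "category": "TIR_ONLY",
             "tir_start": len(leader) + 1, "tir_end": len(leader) + len(tir)}
    return rec, truth


def make_lrr_only(rng: np.random.Generator, seq_id: str, species: str,
                  n_lrr: int = 5, noise: float = 0.0) -> tuple[SequenceRecord, dict]:
    unit_len = int(rng.integers(22, 27))
    unit = (LRR_CONSENSUS_UNIT * 2)[:unit_len]
    leader = _bg(rng, int(rng.integers(15, 31)), allow_c=False)
    body = "".join(_noisy(rng, unit, noise) for _ in range(n_lrr))
    cap = _cap(rng)
    tail = _bg(rng, int(rng.integers(10, 31)), allow_c=False)
    rec = SequenceRecord(
        id=seq_id,
        residues=leader + body + _bg(rng, 5, allow_c=False) + cap + tail,
        species=species,
    )
    return rec, {"seq_id": seq_id, "category": "LRR_ONLY", "n_lrr": n_lrr}


def make_background(rng: np.random.Generator, seq_id: str, species: str,
                    min_len: int = 150, max_len: int = 500) -> tuple[SequenceRecord, dict]:
    n = int(rng.integers(min_len, max_len + 1))
    rec = SequenceRecord(id=seq_id, residues=_bg(rng, n), species=species)
    return rec, {"seq_id": seq_id, "category": "NONE"}


def make_proteome(
    n_tlr: int = 3,
    n_tir_only: int = 2,
    n_lrr_only: int = 2,
    n_background: int = 10,
    isoform_pairs: int = 0,
    seed: int | None = None,
    species: str = "synthetic_sp",
    noise: float = 0.0,
    target_identity: float = 0.95,
) -> tuple[list[SequenceRecord], dict]:
    """A mixed proteome of planted receptors, decoys, background proteins and
    isoform pairs mutated to ``target_identity``."""
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truth: dict = {
        "seed": seed, "species": species, "receptors": [],
        "isoform_clusters": [], "categories": {},
    }

    for i in range(n_tlr):
        tlr_type = "scc" if i % 2 == 0 else "mcc"
        rec, t = make_tlr_sequence(
            tlr_type, n_lrr=int(rng.integers(4, 11)), rng=rng, noise=noise,
            seq_id=f"tlr_{i:04d}", species=species,
        )
        records.append(rec)
        truth["receptors"].append(t)
        truth["categories"][rec.id] = "TLR"
    for i in range(n_tir_only):
        rec, t = make_tir_only(rng, f"tironly_{i:04d}", species, noise=noise)
        records.append(rec)
        truth["categories"][rec.id] = "TIR_ONLY"
    for i in range(n_lrr_only):
        rec, t = make_lrr_only(rng, f"lrronly_{i:04d}", species, noise=noise)
        records.append(rec)
        truth["categories"][rec.id] = "LRR_ONLY"
    for i in range(n_background):
        rec, t = make_background(rng, f"bg_{i:04d}", species)
        records.append(rec)
        truth["categories"][rec.id] = "NONE"
    for i in range(isoform_pairs):
        rec, t = make_tlr_sequence(
            "scc", n_lrr=int(rng.integers(5, 9)), rng=rng, noise=noise,
            seq_id=f"iso_{i:04d}a", species=species,
        )
        n_subs = int(round((1.0 - target_identity) * len(rec.residues)))
        iso = SequenceRecord(
            id=f"iso_{i:04d}b",
            residues=_mutate(rng, rec.residues, n_subs),
            species=species,
        )
        records.extend([rec, iso])
        truth["receptors"].append(t)
        truth["categories"][rec.id] = "TLR"
        truth["categories"][iso.id] = "TLR"
        truth["isoform_clusters"].append([rec.id, iso.id])
    return records, truth


# ---------------------------------------------------------------------------
# clade evolution on a species tree

def simulate_clade_evolution(
    tree: dendropy.Tree,
    characters: Sequence[str],
    loss_rate: float,
    seed: int | None = None,
    gain_nodes: Mapping[str, str] | None = None,
    max_tries: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Single-origin gain plus independent edge losses (no regain).

    Each character gains at a fixed or randomly drawn internal node, then is
    dropped on each descendant edge with probability ``loss_rate``. A
    replicate leaving no presence leaf is redrawn (up to ``max_tries``).
    """
    if not (0 <= loss_rate < 1):
        raise ValueError("loss_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    taxa = sorted(leaf_labels(tree.seed_node))
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]

    def node_name(node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or ""

    matrix = pd.DataFrame(False, index=taxa, columns=list(characters))
    truth: dict = {"seed": seed, "loss_rate": loss_rate, "characters": {}}
    for char in characters:
        if gain_nodes and char in gain_nodes:
            gain = next(n for n in internal if node_name(n) == gain_nodes[char])
        else:
            gain = internal[int(rng.integers(len(internal)))]
        for _ in range(max_tries):
            losses: list[str] = []
            present_leaves: list[str] = []

            def descend(node: dendropy.Node) -> None:
                for child in node.child_nodes():
                    if rng.random() < loss_rate:
                        losses.append(node_name(child) or "unnamed")
                        continue
                    if child.is_leaf():
                        present_leaves.append(child.taxon.label)
                    else:
                        descend(child)

            if gain.is_leaf():  # cannot happen: internal only
                present_leaves.append(node_name(gain))
            else:
                descend(gain)
            if present_leaves:
                break
        if not present_leaves:
            raise RuntimeError("could not simulate a surviving character")
        matrix.loc[present_leaves, char] = True
        truth["characters"][char] = {
            "gain_node": node_name(gain),
            "loss_edges": sorted(losses),
            "present": sorted(present_leaves),
        }
    return matrix, truth


# ---------------------------------------------------------------------------
# alignments with planted insertions

def simulate_alignment_with_insertion(
    n_carriers: int,
    n_noncarriers: int,
    n_cols: int,
    window: tuple[int, int],
    seed: int | None = None,
    gap_fraction: float = 0.1,
) -> tuple[Alignment, dict]:
    """Carriers hold residues across the window columns; non-carriers are
    fully gapped there. Remaining cells are gapped at ``gap_fraction``."""
    start, end = window
    if not (1 <= start <= end <= n_cols):
        raise ValueError("window outside alignment columns")
    rng = np.random.default_rng(seed)
    rows = []
    carriers = [f"carrier_{i:03d}" for i in range(n_carriers)]
    noncarriers = [f"noncarrier_{i:03d}" for i in range(n_noncarriers)]
    for sid in carriers + noncarriers:
        is_carrier = sid.startswith("carrier")
        chars = []
        for col in range(1, n_cols + 1):
            in_window = start <= col <= end
            if in_window:
                chars.append(str(rng.choice(_BG_AA, p=_BG_P)) if is_carrier else "-")
            elif rng.random() < gap_fraction:
                chars.append("-")
            else:
                chars.append(str(rng.choice(_BG_AA, p=_BG_P)))
        rows.append((sid, "".join(chars)))
    truth = {"seed": seed, "carriers": carriers, "window": [start, end]}
    return Alignment(tuple(rows)), truth


# ---------------------------------------------------------------------------
# expression matrices

def simulate_expression(
    n_genes: int,
    stages: Sequence[str] | int,
    expressed_profiles: Mapping[str, str] | None = None,
    libsize_fold: float = 3.0,
    seed: int | None = None,
    margin: float = 2.0,
    dispersion: float = 0.1,
    threshold: float = 0.15,
    n_housekeeping: int = 200,
) -> tuple[CountMatrix, dict]:
    """Stage x gene counts with known expressed/silent structure.

    Focal genes (``tlr_0000`` ...) are planted as ``throughout``,
    ``windowed`` or ``not_detected``; a housekeeping block stabilises the TPM
    denominator. Counts are negative-binomial; expressed cells are
    floor-clamped so their realised TPM clears ``threshold * margin``, which
    is the generator's contract with its truth record.
    """
    if libsize_fold < 1:
        raise ValueError("libsize_fold must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(stages, int):
        stages = [f"stage_{i:02d}" for i in range(stages)]
    stages = list(stages)
    n_stages = len(stages)
    if n_stages < 2:
        raise ValueError("need at least 2 stages")

    genes = [f"tlr_{i:04d}" for i in range(n_genes)]
    classes: dict[str, str] = {}
    expressed: dict[str, list[bool]] = {}
    class_choices = ("throughout", "windowed", "not_detected")
    for g in genes:
        cls = (expressed_profiles or {}).get(g) or class_choices[int(rng.integers(3))]
        if cls == "throughout":
            pattern = [True] * n_stages
        elif cls == "not_detected":
            pattern = [False] * n_stages
        elif cls == "windowed":
            w = int(rng.integers(1, n_stages))
            s0 = int(rng.integers(0, n_stages - w + 1))
            pattern = [s0 <= i < s0 + w for i in range(n_stages)]
        else:
            raise ValueError(f"unknown temporal class {cls!r}")
        classes[g] = cls
        expressed[g] = pattern

    hk = [f"hk_{i:04d}" for i in range(n_housekeeping)]
    all_genes = genes + hk
    eff_len = pd.DataFrame(
        np.tile(rng.integers(500, 3001, size=len(all_genes)).astype(float)[:, None],
                (1, n_stages)),
        index=all_genes, columns=stages,
    )

    # planted per-stage true TPM
    tpm_true = pd.DataFrame(0.0, index=all_genes, columns=stages)
    for g in genes:
        for i, on in enumerate(expressed[g]):
            if on:
                tpm_true.iloc[tpm_true.index.get_loc(g), i] = (
                    threshold * margin * rng.uniform(1.0, 6.0)
                )
    hk_raw = rng.lognormal(mean=3.0, sigma=1.0, size=n_housekeeping)
    for i, stage in enumerate(stages):
        budget = 1e6 - tpm_true[stage].sum()
        tpm_true.loc[hk, stage] = hk_raw / hk_raw.sum() * budget

    base_depth = 5e4
    depths = base_depth * rng.uniform(1.0, libsize_fold, size=n_stages)
    nb_n = 1.0 / dispersion
    counts = pd.DataFrame(0.0, index=all_genes, columns=stages)
    for i, stage in enumerate(stages):
        mean = tpm_true[stage].to_numpy() / 1e6 * eff_len[stage].to_numpy() * depths[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = nb_n / (nb_n + mean)
        sampled = np.where(mean > 0, rng.negative_binomial(nb_n, np.where(mean > 0, p, 1.0)), 0)
        counts[stage] = sampled.astype(float)

    # enforce the margin contract on realised TPM for expressed cells
    for i, stage in enumerate(stages):
        rates = counts[stage] / eff_len[stage]
        for g in genes:
            if expressed[g][i]:
                denom = rates.drop(g).sum()
                # smallest count giving TPM >= threshold*margin given the others
                need = threshold * margin / 1e6
                min_rate = need * denom / (1.0 - need)
                min_count = int(np.ceil(min_rate * eff_len.at[g, stage]))
                if counts.at[g, stage] < min_count:
                    counts.at[g, stage] = float(min_count)

    matrix = CountMatrix(counts=counts, eff_lengths=eff_len)
    truth = {
        "seed": seed,
        "genes": genes,
        "classes": classes,
        "expressed": {g: expressed[g] for g in genes},
        "depths": {s: float(d) for s, d in zip(stages, depths)},
        "threshold": threshold,
        "margin": margin,
    }
    return matrix, truth
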