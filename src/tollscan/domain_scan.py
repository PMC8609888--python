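"""Domain-architecture scanning for TLR candidates.

Annotates four kinds of features on a protein sequence:

* ``LRR`` — leucine-rich repeat units, found with a position-weight profile
  of the canonical LxxLxLxxNxL motif and tiled into non-overlapping units.
* ``LRRNT`` / ``LRRCT`` — cysteine-cap modules flanking LRR arrays, found
  with a four-cysteine spacing pattern.
* ``TM`` — a single-pass transmembrane segment, found by Kyte–Doolittle
  sliding-window hydropathy.
* ``TIR`` — the intracellular signalling domain, scored against a bundled
  position-specific profile built from a packaged seed alignment.

All coordinates are 1-based inclusive. Scanning is deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np

from tollscan.records import SequenceRecord

# ---------------------------------------------------------------------------
# basic types

DOMAIN_KINDS = ("LRR", "LRRNT", "LRRCT", "TM", "TIR")


@dataclass(frozen=True, order=True)
class DomainHit:
    start: int  # 1-based
    end: int    # 1-based inclusive
    kind: str
    score: float

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad hit coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Architecture:
    """Resolved, ordered domain annotation for one sequence."""

    seq_id: str
    hits: tuple[DomainHit, ...]
    length: int
    n_lrr: int
    n_lrrct: int
    has_lrrnt: bool
    has_tm: bool
    has_tir: bool
    complete: bool

    def hits_of(self, kind: str) -> list[DomainHit]:
        return [h for h in self.hits if h.kind == kind]

    @property
    def tm(self) -> Optional[DomainHit]:
        hits = self.hits_of("TM")
        return hits[0] if hits else None

    @property
    def tir(self) -> Optional[DomainHit]:
        hits = self.hits_of("TIR")
        return hits[0] if hits else None


# ---------------------------------------------------------------------------
# sequence encoding

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_AA_INDEX["X"] = 20  # scores zero everywhere


def _encode(residues: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in residues), dtype=np.int64, count=len(residues))


# ---------------------------------------------------------------------------
# LRR repeats

# Canonical 24-residue repeat used by the synthetic generator; the scanner
# only relies on the 11-residue LxxLxLxxNxL core.
LRR_CONSENSUS_UNIT = "LSSLSLSSNSLTESTPESTQESTA"
LRR_MOTIF_LEN = 11
DEFAULT_LRR_THRESHOLD = 11.5

_HYDROPHOBIC_KEY = {"L": 2.0, "I": 1.5, "V": 1.5, "M": 1.5, "F": 1.2}
_ASN_KEY = {"N": 2.0, "D": 1.5, "S": 1.5, "T": 1.5, "Q": 1.5, "C": 1.0}
_SPACER = {"S": 1.0, "A": 0.5, "T": 0.5}


def _lrr_profile() -> np.ndarray:
    """(11, 21) weight matrix for the LxxLxLxxNxL core."""
    prof = np.zeros((LRR_MOTIF_LEN, 21))
    for pos in range(LRR_MOTIF_LEN):
        table = _SPACER
        if pos in (0, 3, 5, 10):
            table = _HYDROPHOBIC_KEY
        elif pos == 8:
            table = _ASN_KEY
        for aa, w in table.items():
            prof[pos, _AA_INDEX[aa]] = w
    return prof


_LRR_PROFILE = _lrr_profile()
LRR_PROFILE_MAX = float(_LRR_PROFILE.max(axis=1).sum())


def _profile_scores(encoded: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Score of the profile placed at every start position (vectorised)."""
    m = profile.shape[0]
    n = len(encoded) - m + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    for j in range(m):
        scores += profile[j, encoded[j:j + n]]
    return scores


def find_lrr_repeats(
    record: SequenceRecord,
    min_unit: int = 22,
    max_unit: int = 26,
    threshold: float = DEFAULT_LRR_THRESHOLD,
) -> list[DomainHit]:
    """Locate LRR units as non-overlapping motif anchors tiled into repeats.

    Candidate anchors (motif score >= ``threshold``) are accepted greedily by
    descending score; anchors closer than ``min_unit`` to an accepted one are
    discarded. Unit extents are inferred from the spacing of consecutive
    anchors; isolated anchors fall back to the 24-residue canonical length.
    """
    encoded = _encode(record.residues)
    scores = _profile_scores(encoded, _LRR_PROFILE)
    candidates = np.flatnonzero(scores >= threshold)
    if candidates.size == 0:
        return []
    order = sorted(candidates, key=lambda i: (-scores[i], i))
    accepted: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_unit for j in accepted):
            accepted.append(int(i))
    accepted.sort()

    spacings = [b - a for a, b in zip(accepted, accepted[1:]) if min_unit <= b - a <= max_unit]
    default_len = int(np.median(spacings)) if spacings else 24
    default_len = max(min_unit, min(max_unit, default_len))

    hits: list[DomainHit] = []
    n = len(record.residues)
    for k, start0 in enumerate(accepted):
        nxt = accepted[k + 1] if k + 1 < len(accepted) else None
        if nxt is not None and min_unit <= nxt - start0 <= max_unit:
            unit_len = nxt - start0
        else:
            unit_len = default_len
            if nxt is not None:
                unit_len = min(unit_len, nxt - start0)
        end0 = min(start0 + unit_len - 1, n - 1)
        if end0 - start0 + 1 < min_unit:
            continue
        hits.append(DomainHit(start=start0 + 1, end=end0 + 1, kind="LRR",
                              score=float(scores[start0])))
    return hits


def group_lrr_arrays(lrr_hits: Iterable[DomainHit], max_gap: int = 10) -> list[tuple[int, int]]:
    """Merge adjacent LRR hits (gap <= ``max_gap``) into (start, end) arrays."""
    arrays: list[tuple[int, int]] = []
    for hit in sorted(lrr_hits):
        if arrays and hit.start - arrays[-1][1] - 1 <= max_gap:
            arrays[-1] = (arrays[-1][0], max(arrays[-1][1], hit.end))
        else:
            arrays.append((hit.start, hit.end))
    return arrays


# ---------------------------------------------------------------------------
# cysteine caps

# C-x(2..20)-C-x(2..30)-C-x(2..30)-C, minimal (non-greedy) spans
_CAP_PATTERN = re.compile(r"C[^C]{2,20}C[^C]{2,30}C[^C]{2,30}C")
CAP_FLANK_WINDOW = 60


def _cap_matches(residues: str, lo0: int, hi0: int) -> list[tuple[int, int]]:
    """All non-overlapping cap clusters inside [lo0, hi0) (0-based)."""
    window = residues[lo0:hi0]
    return [(lo0 + m.start(), lo0 + m.end() - 1) for m in _CAP_PATTERN.finditer(window)]


def find_cysteine_caps(
    record: SequenceRecord,
    lrr_hits: list[DomainHit],
    flank: int = CAP_FLANK_WINDOW,
) -> list[DomainHit]:
    """Find LRRNT/LRRCT four-cysteine clusters flanking LRR arrays.

    The N-flank of the first array is searched for an LRRNT; the C-flank of
    every array is searched for LRRCT clusters, so each array of a
    multiple-cysteine-cluster receptor contributes its own cap.
    """
    arrays = group_lrr_arrays(lrr_hits)
    if not arrays:
        return []
    residues = record.residues
    hits: list[DomainHit] = []
    first_start0 = arrays[0][0] - 1
    for s0, e0 in _cap_matches(residues, max(0, first_start0 - flank), first_start0):
        hits.append(DomainHit(start=s0 + 1, end=e0 + 1, kind="LRRNT", score=4.0))
    for _, a_end in arrays:
        for s0, e0 in _cap_matches(residues, a_end, min(len(residues), a_end + flank)):
            hits.append(DomainHit(start=s0 + 1, end=e0 + 1, kind="LRRCT", score=4.0))
    # drop duplicates (a cluster can flank two arrays when they are close)
    seen: set[tuple[int, int]] = set()
    unique = []
    for h in sorted(hits):
        if (h.start, h.end) not in seen:
            seen.add((h.start, h.end))
            unique.append(h)
    return unique


# ---------------------------------------------------------------------------
# transmembrane segment

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}
TM_MIN_LEN = 17
TM_MAX_LEN = 25


def find_transmembrane(
    record: SequenceRecord,
    window: int = 19,
    threshold: float = 1.6,
) -> list[DomainHit]:
    """Sliding Kyte–Doolittle mean hydropathy; one hit per above-threshold run.

    Within each run the best window is extended on both sides while flanking
    residues remain hydrophobic, capped at ``TM_MAX_LEN`` residues. Hits are
    returned sorted by descending score.
    """
    n = len(record.residues)
    if n < window:
        return []
    kd = np.array([KYTE_DOOLITTLE[c] for c in record.residues])
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    above = means >= threshold
    hits: list[DomainHit] = []
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(above) and above[j + 1]:
            j += 1
        run = means[i:j + 1]
        best = i + int(np.argmax(run))
        lo, hi = best, best + window - 1  # 0-based inclusive
        while hi - lo + 1 < TM_MAX_LEN:
            left = kd[lo - 1] if lo > 0 else -np.inf
            right = kd[hi + 1] if hi < n - 1 else -np.inf
            if left <= 0 and right <= 0:
                break
            if left >= right:
                lo -= 1
            else:
                hi += 1
        hits.append(DomainHit(start=lo + 1, end=hi + 1, kind="TM",
                              score=float(means[best])))
        i = j + 1
    hits.sort(key=lambda h: (-h.score, h.start))
    return hits


# ---------------------------------------------------------------------------
# TIR domain

DEFAULT_TIR_THRESHOLD = 0.5


def _load_tir_seed() -> list[str]:
    text = resources.files("tollscan.data").joinpath("tir_seed.fasta").read_text()
    seqs, cur = [], []
    for line in text.splitlines():
        if line.startswith(">"):
            if cur:
                seqs.append("".join(cur))
            cur = []
        elif line.strip():
            cur.append(line.strip())
    if cur:
        seqs.append("".join(cur))
    return seqs


def _tir_profile() -> tuple[np.ndarray, str]:
    """Credit matrix from the packaged seed alignment.

    Full credit for the consensus (first seed) residue, half credit for any
    other residue observed at that column in the seed set.
    """
    seqs = _load_tir_seed()
    length = len(seqs[0])
    prof = np.zeros((length, 21))
    for pos in range(length):
        observed = {s[pos] for s in seqs}
        for aa in observed:
            prof[pos, _AA_INDEX[aa]] = 0.5
        prof[pos, _AA_INDEX[seqs[0][pos]]] = 1.0
    return prof, seqs[0]


_TIR_PROFILE, TIR_CONSENSUS = _tir_profile()
TIR_PROFILE_LEN = _TIR_PROFILE.shape[0]


def find_tir(
    record: SequenceRecord,
    threshold: float = DEFAULT_TIR_THRESHOLD,
) -> Optional[DomainHit]:
    """Best TIR profile placement, or ``None`` below the calibrated threshold."""
    if len(record.residues) < TIR_PROFILE_LEN:
        return None
    encoded = _encode(record.residues)
    scores = _profile_scores(encoded, _TIR_PROFILE) / TIR_PROFILE_LEN
    best = int(np.argmax(scores))
    if scores[best] < threshold:
        return None
    return DomainHit(start=best + 1, end=best + TIR_PROFILE_LEN, kind="TIR",
                     score=float(scores[best]))


# ---------------------------------------------------------------------------
# full architecture

_PRIORITY = {"TIR": 0, "TM": 1, "LRRNT": 2, "LRRCT": 2, "LRR": 3}
FRAGMENT_MARGIN = 5


def annotate_architecture(
    record: SequenceRecord,
    tm_window: int = 19,
    tm_threshold: float = 1.6,
    lrr_threshold: float = DEFAULT_LRR_THRESHOLD,
    tir_threshold: float = DEFAULT_TIR_THRESHOLD,
) -> Architecture:
    """Run all detectors and resolve them into one :class:`Architecture`.

    Overlaps are resolved with priority TIR > TM > caps > LRR. When several
    TM candidates exist and a TIR is present, the chosen TM is the
    best-scoring candidate lying N-terminal of the TIR, keeping the
    TM-before-TIR topology of a genuine receptor.
    """
    if len(record.residues) == 0:  # defensive; SequenceRecord already forbids
        raise ValueError("cannot annotate an empty sequence")

    tir = find_tir(record, threshold=tir_threshold)
    tms = find_transmembrane(record, window=tm_window, threshold=tm_threshold)
    if tir is not None:
        tms = [h for h in tms if h.end < tir.start]
    tm = tms[0] if tms else None

    resolved: list[DomainHit] = [h for h in (tir, tm) if h is not None]

    lrrs = find_lrr_repeats(record, threshold=lrr_threshold)
    lrrs = [h for h in lrrs if not any(h.overlaps(r) for r in resolved)]
    if tir is not None and tm is not None:
        # receptor topology: the LRR region is extracellular (N-terminal of TM)
        lrrs = [h for h in lrrs if h.end < tm.start]
    caps = find_cysteine_caps(record, lrrs)
    caps = [h for h in caps if not any(h.overlaps(r) for r in resolved)]
    resolved.extend(caps)
    lrrs = [h for h in lrrs if not any(h.overlaps(c) for c in caps)]
    resolved.extend(lrrs)
    resolved.sort(key=lambda h: (h.start, _PRIORITY[h.kind]))

    n = len(record.residues)
    complete = True
    if resolved:
        if min(h.start for h in resolved) <= FRAGMENT_MARGIN:
            complete = False
        if max(h.end for h in resolved) > n - FRAGMENT_MARGIN:
            complete = False

    return Architecture(
        seq_id=record.id,
        hits=tuple(resolved),
        length=n,
        n_lrr=sum(1 for h in resolved if h.kind == "LRR"),
        n_lrrct=sum(1 for h in resolved if h.kind == "LRRCT"),
        has_lrrnt=any(h.kind == "LRRNT" for h in resolved),
        has_tm=tm is not None,
        has_tir=tir is not None,
        complete=complete,
    )


def architecture_table(archs: Iterable[Architecture]) -> list[dict]:
    """Flatten architectures into GFF3-style rows (seq_id, source, kind, ...)."""
    rows = []
    for arch in archs:
        for h in arch.hits:
            rows.append({
                "seq_id": arch.seq_id,
                "source": "tollscan",
                "kind": h.kind,
                "start": h.start,
                "end": h.end,
                "score": round(h.score, 4),
            })
    return rows
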