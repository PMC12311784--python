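"""De novo sequence tags from fragment ladders and homology identification.

Tags are read from consecutive mass gaps in a deconvolved fragment-mass
list via a spectrum graph; proteins are then identified by an ungapped
high-scoring-pair (HSP) search of the tags against a FASTA database.

Scoring scheme (fixed for this artifact): match +2, mismatch -1, no gaps,
with I/L and K/Q treated as equivalent.  Totals are comparable within this
implementation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .masscore import MODIFICATIONS, RESIDUE_MASSES

__all__ = [
    "SequenceTag",
    "HSP",
    "ProteinHit",
    "extract_tags",
    "hsp_search",
    "MATCH_SCORE",
    "MISMATCH_SCORE",
    "MIN_HSP_SCORE",
]

MATCH_SCORE = 2
MISMATCH_SCORE = -1
MIN_HSP_SCORE = 6


@dataclass(frozen=True)
class SequenceTag:
    """A residue string read from consecutive fragment-mass gaps.

    I/L gaps are emitted as ``L``; K vs Q is decided by closest mass, with
    positions where both fit within tolerance recorded in ``ambiguous``.
    Flanking masses are the first and last peak of the supporting path.
    """

    residues: str
    prefix_mass: float
    suffix_mass: float
    series: str = ""
    ambiguous: tuple[int, ...] = ()  # 0-based positions with K/Q ambiguity

    def __len__(self) -> int:
        return len(self.residues)


def _gap_alphabet(extra_mod_deltas: Mapping[str, float] | None) -> list[tuple[float, str, bool]]:
    """(mass, emitted letter, kq_ambiguous_candidate) gap entries."""
    entries: list[tuple[float, str, bool]] = []
    for aa, mass in RESIDUE_MASSES.items():
        if aa == "I":
            continue  # I/L collapse: L carries both
        entries.append((mass, aa, aa in ("K", "Q")))
    if extra_mod_deltas:
        for label, delta in extra_mod_deltas.items():
            entries.append((delta, label, False))
    entries.sort()
    return entries


def _gap_residue(
    gap: float, tol_da: float, alphabet: Sequence[tuple[float, str, bool]]
) -> tuple[str, bool] | None:
    """Best residue letter for a mass gap, or None; flags K/Q ambiguity."""
    best = None
    hits = []
    for mass, letter, kq in alphabet:
        err = abs(gap - mass)
        if err <= tol_da:
            hits.append((err, letter, kq))
    if not hits:
        return None
    hits.sort()
    err, letter, _ = hits[0]
    kq_hits = [h for h in hits if h[2]]
    ambiguous = letter in ("K", "Q") and len(kq_hits) > 1
    return letter, ambiguous


def extract_tags(
    peaks: Sequence[float],
    tol_da: float = 0.01,
    residue_table: Mapping[str, float] | None = None,
    ptm_deltas: Mapping[str, float] | None = None,
    min_length: int = 2,
    series: str = "",
) -> list[SequenceTag]:
    """All maximal residue paths through the spectrum graph.

    Nodes are peak masses; an edge u -> v exists when mass(v) - mass(u)
    matches a residue mass within ``tol_da``.  ``ptm_deltas`` optionally
    adds modified-residue gaps (e.g. ``{"K+ac": 170.105}``), off by
    default.  Output order is deterministic: by start mass, then length.
    """
    masses = sorted(set(float(m) for m in peaks))
    if residue_table is None:
        alphabet = _gap_alphabet(ptm_deltas)
    else:
        entries = [(m, aa, aa in ("K", "Q")) for aa, m in residue_table.items() if aa != "I"]
        if ptm_deltas:
            entries += [(d, lbl, False) for lbl, d in ptm_deltas.items()]
        alphabet = sorted(entries)
    if not alphabet:
        return []
    max_gap = max(m for m, _, _ in alphabet) + tol_da

    n = len(masses)
    edges: list[list[tuple[int, str, bool]]] = [[] for _ in range(n)]
    has_incoming = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            gap = masses[j] - masses[i]
            if gap > max_gap:
                break
            hit = _gap_residue(gap, tol_da, alphabet)
            if hit is not None:
                edges[i].append((j, hit[0], hit[1]))
                has_incoming[j] = True

    tags: list[SequenceTag] = []
    seen: set[tuple[str, float]] = set()

    def walk(node: int, letters: list[str], ambig: list[int], start: int) -> None:
        if not edges[node]:
            if len(letters) >= min_length:
                residues = "".join(letters)
                key = (residues, masses[start])
                if key not in seen:
                    seen.add(key)
                    tags.append(
                        SequenceTag(
                            residues,
                            masses[start],
                            masses[node],
                            series,
                            tuple(ambig),
                        )
                    )
            return
        for nxt, letter, is_ambig in edges[node]:
            letters.append(letter)
            if is_ambig:
                ambig.append(len(letters) - 1)
            walk(nxt, letters, ambig, start)
            if is_ambig:
                ambig.pop()
            letters.pop()

    for start in range(n):
        if not has_incoming[start] and edges[start]:
            walk(start, [], [], start)

    tags.sort(key=lambda t: (t.prefix_mass, len(t.residues), t.residues))
    return tags


@dataclass(frozen=True)
class HSP:
    """An ungapped local alignment between one tag and a database protein.

    Coordinates are 0-based half-open; ``subject_start/end`` index the
    database sequence, ``query_start/end`` the tag.
    """

    protein_id: str
    tag_index: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    score: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class ProteinHit:
    protein_id: str
    total_score: int
    hsps: tuple[HSP, ...]
    rank: int = 0


def _residues_match(a: str, b: str) -> bool:
    if a == b:
        return True
    pair = {a, b}
    return pair == {"I", "L"} or pair == {"K", "Q"}


def _diagonal_hsps(
    tag: str, subject: str, protein_id: str, tag_index: int, min_score: int
) -> list[HSP]:
    """All locally maximal ungapped segments with score >= min_score."""
    out: list[HSP] = []
    qn, sn = len(tag), len(subject)
    for offset in range(-(qn - 1), sn):
        q0 = max(0, -offset)
        s0 = q0 + offset
        length = min(qn - q0, sn - s0)
        if length <= 0:
            continue
        cur = 0
        cur_start = 0
        best = 0
        best_span = (0, 0)
        for k in range(length):
            step = (
                MATCH_SCORE
                if _residues_match(tag[q0 + k], subject[s0 + k])
                else MISMATCH_SCORE
            )
            if cur <= 0:
                cur = step
                cur_start = k
            else:
                cur += step
            if cur > best:
                best = cur
                best_span = (cur_start, k + 1)
            if cur < 0:
                if best >= min_score:
                    a, b = best_span
                    out.append(
                        HSP(protein_id, tag_index, q0 + a, q0 + b, s0 + a, s0 + b, best)
                    )
                cur = 0
                best = 0
                best_span = (k + 1, k + 1)
        if best >= min_score:
            a, b = best_span
            out.append(HSP(protein_id, tag_index, q0 + a, q0 + b, s0 + a, s0 + b, best))
    return out


def hsp_search(
    tags: Sequence[SequenceTag | str],
    database: Sequence[tuple[str, str]],
    min_hsp_score: int = MIN_HSP_SCORE,
) -> list[ProteinHit]:
    """Rank database proteins by total non-overlapping HSP score.

    For every tag x protein the best ungapped local alignments are found;
    HSPs scoring below ``min_hsp_score`` are dropped.  A protein's total
    is the sum of its best HSPs chosen greedily by score so that no two
    selected HSPs overlap on subject coordinates.  Ties rank by protein id.
    """
    if not database:
        raise ValueError("database must be non-empty")
    tag_strings = [t.residues if isinstance(t, SequenceTag) else t for t in tags]
    hits: list[ProteinHit] = []
    for protein_id, seq in database:
        all_hsps: list[HSP] = []
        for ti, tag in enumerate(tag_strings):
            if len(tag) == 0:
                continue
            all_hsps.extend(_diagonal_hsps(tag, seq, protein_id, ti, min_hsp_score))
        all_hsps.sort(key=lambda h: (-h.score, h.subject_start, h.tag_index))
        chosen: list[HSP] = []
        for h in all_hsps:
            if all(
                h.subject_end <= c.subject_start or h.subject_start >= c.subject_end
                for c in chosen
            ):
                chosen.append(h)
        total = sum(h.score for h in chosen)
        hits.append(ProteinHit(protein_id, total, tuple(chosen)))
    hits.sort(key=lambda h: (-h.total_score, h.protein_id))
    return [
        ProteinHit(h.protein_id, h.total_score, h.hsps, rank=i + 1)
        for i, h in enumerate(hits)
    ]
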