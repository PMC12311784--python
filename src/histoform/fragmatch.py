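"""Fragment-ladder matching and the four proteoform scores.

A matched spectrum is scored by sequence coverage (%SC: residues bracketed
by evidenced cleavage sites), sequence validation percentage (%SVP:
terminal-contiguous confirmed residues), intensity coverage (%IC: matched
fraction of total peak intensity), and their product MS = %SC x %IC / 100.

A residue is "confirmed" when both of its flanking cleavage sites are
evidenced by a matched fragment (the two termini count as evidenced).
Each observed peak is assigned to at most one theoretical fragment — the
one with smallest |ppm error| — so intensity is never double counted.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .masscore import (
    C_TERMINAL_SERIES,
    N_TERMINAL_SERIES,
    FragmentIon,
    Proteoform,
    fragment_ladder,
    mz_from_mass,
)

__all__ = [
    "SpectrumPeaks",
    "FragmentMatch",
    "MatchResult",
    "ScoreConfig",
    "ECD_SERIES",
    "CID_SERIES",
    "match_fragments",
    "sequence_coverage",
    "sequence_validation_pct",
    "intensity_coverage",
    "ms_score",
    "score_proteoform",
    "rank_candidates",
]

ECD_SERIES: tuple[str, ...] = ("c", "zdot", "a")
CID_SERIES: tuple[str, ...] = ("b", "y")

# deterministic tie-break order between series
_SERIES_ORDER = {s: i for i, s in enumerate(("c", "zdot", "z", "b", "y", "a"))}


@dataclass(frozen=True)
class SpectrumPeaks:
    """Centroided observed peaks, sorted by value.

    ``mode`` is ``"neutral"`` (deconvolved neutral fragment masses) or
    ``"mz"``.  Construction sorts peaks and sums intensities of exact
    duplicates so values are strictly increasing.
    """

    values: tuple[float, ...]
    intensities: tuple[float, ...]
    mode: str = "neutral"
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    title: str = ""

    def __post_init__(self):
        if self.mode not in ("neutral", "mz"):
            raise ValueError(f"unknown spectrum mode {self.mode!r}")
        if len(self.values) != len(self.intensities):
            raise ValueError("values and intensities length mismatch")
        if any(i < 0 or not np.isfinite(i) for i in self.intensities):
            raise ValueError("intensities must be finite and non-negative")
        pairs: dict[float, float] = {}
        for v, i in zip(self.values, self.intensities):
            pairs[v] = pairs.get(v, 0.0) + i
        ordered = sorted(pairs.items())
        object.__setattr__(self, "values", tuple(v for v, _ in ordered))
        object.__setattr__(self, "intensities", tuple(i for _, i in ordered))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def total_intensity(self) -> float:
        return float(sum(self.intensities))


@dataclass(frozen=True)
class FragmentMatch:
    fragment: FragmentIon
    peak_index: int
    error_ppm: float


@dataclass(frozen=True)
class MatchResult:
    proteoform: Proteoform
    matches: tuple[FragmentMatch, ...]
    sc_pct: float
    svp_pct: float
    ic_pct: float
    ms: float


@dataclass(frozen=True)
class ScoreConfig:
    series_set: tuple[str, ...] = ECD_SERIES
    tol_ppm: float = 10.0
    max_charge: int = 1

    def __post_init__(self):
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.max_charge < 1:
            raise ValueError("max_charge must be >= 1")


def match_fragments(
    p: Proteoform,
    peaks: SpectrumPeaks,
    series_set: Iterable[str] = ECD_SERIES,
    tol_ppm: float = 10.0,
    max_charge: int = 1,
) -> list[FragmentMatch]:
    """Assign each observed peak to its best theoretical fragment.

    In ``mz`` mode charges 1..max_charge are enumerated.  Ties are broken
    by lower charge, then series order c, z•, z, b, y, a, then lower index.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not len(peaks):
        return []
    theo = fragment_ladder(p, series_set)
    entries: list[tuple[float, FragmentIon]] = []
    if peaks.mode == "mz":
        if max_charge < 1:
            raise ValueError("max_charge must be >= 1 in m/z mode")
        for f in theo:
            for z in range(1, max_charge + 1):
                entries.append(
                    (mz_from_mass(f.neutral_mass, z), FragmentIon(f.series, f.index, f.neutral_mass, z))
                )
    else:
        entries = [(f.neutral_mass, f) for f in theo]
    entries.sort(key=lambda e: e[0])
    theo_values = [e[0] for e in entries]

    matches: list[FragmentMatch] = []
    for pi, obs in enumerate(peaks.values):
        lo = bisect.bisect_left(theo_values, obs * (1 - tol_ppm * 1e-6) - 1e-9)
        hi = bisect.bisect_right(theo_values, obs * (1 + tol_ppm * 1e-6) + 1e-9)
        best = None
        for t_val, frag in entries[lo:hi]:
            err_ppm = (obs - t_val) / t_val * 1e6
            if abs(err_ppm) > tol_ppm:
                continue
            key = (
                abs(err_ppm),
                frag.charge or 0,
                _SERIES_ORDER.get(frag.series, 99),
                frag.index,
            )
            if best is None or key < best[0]:
                best = (key, frag, err_ppm)
        if best is not None:
            matches.append(FragmentMatch(best[1], pi, best[2]))
    return matches


def _cleavage_sites(matches: Iterable[FragmentMatch], n: int) -> set[int]:
    sites = {0, n}
    for m in matches:
        if m.fragment.series in N_TERMINAL_SERIES:
            sites.add(m.fragment.index)
        else:
            sites.add(n - m.fragment.index)
    return sites


def confirmed_residues(matches: Iterable[FragmentMatch], n: int) -> set[int]:
    """Residues whose flanking cleavage sites are both evidenced."""
    sites = _cleavage_sites(matches, n)
    return {k for k in range(1, n + 1) if k - 1 in sites and k in sites}


def sequence_coverage(matches: Iterable[FragmentMatch], n: int) -> float:
    """%SC: confirmed residues / total residues x 100."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    return 100.0 * len(confirmed_residues(matches, n)) / n


def sequence_validation_pct(matches: Iterable[FragmentMatch], n: int) -> float:
    """%SVP: contiguous confirmed residues from the two terminals / n x 100.

    Prefix and suffix runs are counted on disjoint residue sets.
    """
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    confirmed = confirmed_residues(matches, n)
    prefix = 0
    while prefix < n and (prefix + 1) in confirmed:
        prefix += 1
    suffix = 0
    while suffix < n - prefix and (n - suffix) in confirmed:
        suffix += 1
    return 100.0 * (prefix + suffix) / n


def intensity_coverage(
    matches: Iterable[FragmentMatch], peaks: SpectrumPeaks
) -> float:
    """%IC: intensity of peaks holding a match (each once) / total x 100."""
    total = peaks.total_intensity
    if total <= 0:
        raise ValueError("total peak intensity must be positive")
    matched_idx = {m.peak_index for m in matches}
    matched = sum(peaks.intensities[i] for i in matched_idx)
    return 100.0 * matched / total


def ms_score(sc_pct: float, ic_pct: float) -> float:
    """MS = %SC x %IC on a 0-100 scale."""
    if not (0 <= sc_pct <= 100 and 0 <= ic_pct <= 100):
        raise ValueError("scores must lie in [0, 100]")
    return sc_pct * ic_pct / 100.0


def score_proteoform(
    p: Proteoform, peaks: SpectrumPeaks, config: ScoreConfig = ScoreConfig()
) -> MatchResult:
    """Match and compute %SC, %SVP, %IC, and MS for one proteoform."""
    n = len(p.sequence)
    if not len(peaks):
        return MatchResult(p, (), 0.0, 0.0, 0.0, 0.0)
    matches = tuple(
        match_fragments(p, peaks, config.series_set, config.tol_ppm, config.max_charge)
    )
    sc = sequence_coverage(matches, n)
    svp = sequence_validation_pct(matches, n)
    ic = intensity_coverage(matches, peaks) if peaks.total_intensity > 0 else 0.0
    return MatchResult(p, matches, sc, svp, ic, ms_score(sc, ic))


def rank_candidates(
    candidates: Sequence[Proteoform],
    peaks: SpectrumPeaks,
    config: ScoreConfig = ScoreConfig(),
) -> list[MatchResult]:
    """Score candidates and rank by MS descending; ties by %SC descending,
    then fewer modifications, then notation (deterministic)."""
    results = [score_proteoform(p, peaks, config) for p in candidates]
    results.sort(
        key=lambda r: (
            -r.ms,
            -r.sc_pct,
            len(r.proteoform.mods),
            r.proteoform.notation(),
        )
    )
    return results
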