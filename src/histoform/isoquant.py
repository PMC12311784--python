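"""Positional-isomer reporter ions and relative-abundance quantitation.

Within a group of mass-degenerate proteoforms, a reporter ion is a
theoretical fragment of one isomer that lies farther than the matching
tolerance from every fragment of every other member.  Relative abundance
splits the shared MS1 area in proportion to summed reporter intensities.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

from .fragmatch import ECD_SERIES, SpectrumPeaks
from .masscore import FragmentIon, Proteoform, fragment_ladder, proteoform_neutral_mass

__all__ = [
    "IsomerGroup",
    "ReporterSet",
    "IsomerQuantResult",
    "find_reporter_ions",
    "select_balanced_reporters",
    "measure_reporter_intensities",
    "quantify_isomers",
]

GROUPING_TOL_DA = 0.01


@dataclass(frozen=True)
class IsomerGroup:
    """Proteoforms with identical neutral mass sharing one MS1 envelope peak."""

    members: tuple[Proteoform, ...]
    ms1_area: float = 0.0

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an isomer group needs at least 2 members")
        masses = [proteoform_neutral_mass(m) for m in self.members]
        if max(masses) - min(masses) >= GROUPING_TOL_DA:
            raise ValueError(
                "members are not isomeric: mass spread "
                f"{max(masses) - min(masses):.5f} Da >= {GROUPING_TOL_DA} Da"
            )
        if self.ms1_area < 0:
            raise ValueError("ms1_area must be non-negative")


@dataclass(frozen=True)
class ReporterSet:
    group: IsomerGroup
    reporters: tuple[tuple[FragmentIon, ...], ...]  # per member

    def unquantifiable(self) -> tuple[int, ...]:
        """Indices of members that have no reporter ions."""
        return tuple(i for i, r in enumerate(self.reporters) if not r)


@dataclass(frozen=True)
class IsomerQuantResult:
    group: IsomerGroup
    reporter_intensity: tuple[float, ...]
    fractions: tuple[float, ...]
    relative_abundance: tuple[float, ...]
    quantified: bool


def find_reporter_ions(
    group: IsomerGroup,
    series_set: Iterable[str] = ECD_SERIES,
    tol_ppm: float = 10.0,
) -> ReporterSet:
    """Per-member fragments that no other member's ladder can mimic.

    A fragment is a reporter when its mass differs by more than the ppm
    tolerance from every theoretical fragment of every other group member.
    A member may legitimately end up with an empty reporter list (flagged
    via :meth:`ReporterSet.unquantifiable`).
    """
    series_set = tuple(series_set)
    ladders = [fragment_ladder(m, series_set) for m in group.members]
    sorted_masses = [sorted(f.neutral_mass for f in lad) for lad in ladders]

    def shadowed(mass: float, other: list[float]) -> bool:
        tol = tol_ppm * 1e-6 * mass
        i = bisect.bisect_left(other, mass)
        for j in (i - 1, i):
            if 0 <= j < len(other) and abs(other[j] - mass) <= tol:
                return True
        return False

    reporters: list[tuple[FragmentIon, ...]] = []
    for mi, ladder in enumerate(ladders):
        own: list[FragmentIon] = []
        for frag in ladder:
            if not any(
                shadowed(frag.neutral_mass, sorted_masses[oj])
                for oj in range(len(ladders))
                if oj != mi
            ):
                own.append(frag)
        reporters.append(tuple(own))
    return ReporterSet(group, tuple(reporters))


def select_balanced_reporters(
    reporter_set: ReporterSet, per_member: int | None = None
) -> ReporterSet:
    """Equal-size reporter subsets per member.

    Summing raw reporter intensities biases the abundance split toward
    members with larger reporter sets; selecting the same number of
    reporter ions per member removes that bias.  Keeps each member's
    first ``per_member`` reporters (default: the group-wide minimum
    count) in deterministic series/index order.
    """
    counts = [len(r) for r in reporter_set.reporters]
    k = min(counts) if per_member is None else per_member
    trimmed = tuple(
        tuple(sorted(r, key=lambda f: (f.series, f.index))[:k])
        for r in reporter_set.reporters
    )
    return ReporterSet(reporter_set.group, trimmed)


def measure_reporter_intensities(
    reporter_set: ReporterSet,
    peaks: SpectrumPeaks,
    tol_ppm: float = 10.0,
) -> tuple[float, ...]:
    """Summed observed intensity of each member's reporter ions.

    Each observed peak contributes to at most one member (reporters are
    disjoint across members by construction).
    """
    if peaks.mode != "neutral":
        raise ValueError("reporter measurement expects neutral-mass peaks")
    values = peaks.values
    out = []
    for member_reporters in reporter_set.reporters:
        total = 0.0
        used: set[int] = set()
        for frag in member_reporters:
            tol = tol_ppm * 1e-6 * frag.neutral_mass
            i = bisect.bisect_left(values, frag.neutral_mass)
            best = None
            for j in (i - 1, i):
                if 0 <= j < len(values) and j not in used:
                    err = abs(values[j] - frag.neutral_mass)
                    if err <= tol and (best is None or err < best[0]):
                        best = (err, j)
            if best is not None:
                used.add(best[1])
                total += peaks.intensities[best[1]]
        out.append(total)
    return tuple(out)


def quantify_isomers(
    group: IsomerGroup,
    reporter_intensity: Sequence[float],
    ms1_area: float | None = None,
) -> IsomerQuantResult:
    """Split the MS1 area across isomers by reporter-intensity fraction.

    fraction_i = reporters_i / sum(reporters); abundance_i = fraction_i x
    MS1 area.  If all reporter intensities are zero the result is returned
    unquantified with no division performed.
    """
    if len(reporter_intensity) != len(group.members):
        raise ValueError("one reporter intensity per group member required")
    if any(r < 0 for r in reporter_intensity):
        raise ValueError("reporter intensities must be non-negative")
    area = group.ms1_area if ms1_area is None else ms1_area
    if area < 0:
        raise ValueError("ms1_area must be non-negative")
    total = float(sum(reporter_intensity))
    if total == 0:
        zeros = tuple(0.0 for _ in group.members)
        return IsomerQuantResult(group, tuple(reporter_intensity), zeros, zeros, False)
    fractions = tuple(r / total for r in reporter_intensity)
    abundance = tuple(f * area for f in fractions)
    return IsomerQuantResult(group, tuple(reporter_intensity), fractions, abundance, True)
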