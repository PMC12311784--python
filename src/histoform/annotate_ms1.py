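"""Explain deconvolved MS1 neutral-mass shifts and generate proteoform candidates.

An observed intact-mass shift relative to a base sequence is explained as a
combination of PTMs and/or a single amino-acid substitution; candidate
proteoforms with localized modifications are then enumerated for MS/MS
scoring.  Substitutions are kept position-free at this stage — positions
are assigned only by fragment evidence downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .masscore import (
    MODIFICATIONS,
    PROTEIN_N_TERM,
    RESIDUE_MASSES,
    Modification,
    Proteoform,
    proteoform_neutral_mass,
)

__all__ = [
    "DeltaExplanation",
    "MassEnvelope",
    "CandidateSet",
    "LabeledPeak",
    "MassDeficitError",
    "DEFAULT_PTM_ALPHABET",
    "build_delta_table",
    "explain_mass_shift",
    "generate_candidates",
    "annotate_envelope",
]

#: Biological PTM alphabet used throughout (derivatization handled in bottomup).
DEFAULT_PTM_ALPHABET: tuple[str, ...] = ("me1", "me2", "me3", "ac", "ox")

KIND_PTM = "PTM-combo"
KIND_SUBSTITUTION = "substitution"


class MassDeficitError(ValueError):
    """Observed mass lighter than the unmodified base beyond tolerance."""


@dataclass(frozen=True)
class DeltaExplanation:
    """A candidate chemical explanation for an observed mass shift."""

    kind: str  # KIND_PTM | KIND_SUBSTITUTION
    description: str  # e.g. "me2", "ac+me1", "R->K"
    delta: float
    error_da: float | None = None
    error_ppm: float | None = None
    mod_names: tuple[str, ...] = ()

    def with_error(self, delta_obs: float) -> "DeltaExplanation":
        err = self.delta - delta_obs
        ppm = err / abs(delta_obs) * 1e6 if delta_obs else None
        return DeltaExplanation(
            self.kind, self.description, self.delta, err, ppm, self.mod_names
        )


@dataclass(frozen=True)
class MassEnvelope:
    """Deconvolved MS1 neutral-mass peaks: (mass, intensity) pairs."""

    peaks: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self):
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("envelope masses must be strictly increasing")
        if any(i < 0 or i != i for _, i in self.peaks):
            raise ValueError("envelope intensities must be finite and non-negative")

    @property
    def total_intensity(self) -> float:
        return sum(i for _, i in self.peaks)


@dataclass(frozen=True)
class LabeledPeak:
    mass: float
    intensity: float
    label: str
    delta_obs: float
    error_da: float | None


@dataclass(frozen=True)
class CandidateSet:
    base: Proteoform
    observed_mass: float
    candidates: tuple[tuple[Proteoform, float], ...]  # (proteoform, error_da)
    truncated: bool = False


def build_delta_table(
    max_ptms: int = 2,
    ptm_alphabet: Sequence[str | Modification] = DEFAULT_PTM_ALPHABET,
) -> list[DeltaExplanation]:
    """All PTM multisets of size 1..max_ptms plus the 380 ordered
    single-residue substitutions.  Numerically degenerate entries with
    different descriptions are retained."""
    if max_ptms < 1:
        raise ValueError("max_ptms must be >= 1")
    mods = [
        m if isinstance(m, Modification) else MODIFICATIONS[m] for m in ptm_alphabet
    ]
    table: list[DeltaExplanation] = []
    for k in range(1, max_ptms + 1):
        for combo in itertools.combinations_with_replacement(sorted(mods, key=lambda m: m.name), k):
            names = tuple(m.name for m in combo)
            table.append(
                DeltaExplanation(
                    KIND_PTM,
                    "+".join(names),
                    sum(m.delta for m in combo),
                    mod_names=names,
                )
            )
    residues = sorted(RESIDUE_MASSES)
    for x in residues:
        for y in residues:
            if x == y:
                continue
            table.append(
                DeltaExplanation(
                    KIND_SUBSTITUTION,
                    f"{x}->{y}",
                    RESIDUE_MASSES[y] - RESIDUE_MASSES[x],
                )
            )
    return table


def explain_mass_shift(
    delta_obs: float,
    table: Sequence[DeltaExplanation],
    tol_da: float,
) -> list[DeltaExplanation]:
    """Explanations within ``tol_da`` of the observed shift, best first.

    Sorted by |error| ascending; ties put PTM combinations before
    substitutions, then lexicographic description.  An empty list means
    the shift is unexplained — not an error.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    hits = [
        e.with_error(delta_obs) for e in table if abs(e.delta - delta_obs) <= tol_da
    ]
    # |error| rounded to 1e-6 Da so compositionally identical deltas
    # (e.g. me1 vs the G->A substitution, both +CH2) tie exactly; ties
    # then prefer PTM combos over substitutions, fewer modifications
    # (me2 over me1+me1), and finally lexicographic description.
    hits.sort(
        key=lambda e: (
            round(abs(e.error_da), 6),
            0 if e.kind == KIND_PTM else 1,
            len(e.mod_names) if e.mod_names else 1,
            e.description,
        )
    )
    return hits


def _allowed_sites(
    mod: Modification,
    base: Proteoform,
    site_rules: dict[str, set[str]] | None,
) -> list[int]:
    """Open placement sites for one modification on the base proteoform."""
    allowed = (
        site_rules.get(mod.name, set(mod.allowed_sites))
        if site_rules
        else mod.allowed_sites
    )
    sites: list[int] = []
    if (PROTEIN_N_TERM in allowed or "N-TERM" in allowed) and base.mod_at(0) is None:
        sites.append(0)
    for i, aa in enumerate(base.sequence, start=1):
        if aa in allowed and base.mod_at(i) is None:
            sites.append(i)
    return sites


def generate_candidates(
    base: Proteoform,
    observed_mass: float,
    ptm_alphabet: Sequence[str | Modification] = DEFAULT_PTM_ALPHABET,
    site_rules: dict[str, set[str]] | None = None,
    max_mods: int = 6,
    tol_ppm: float = 10.0,
    cap: int = 10_000,
) -> CandidateSet:
    """Enumerate every localized placement of every PTM multiset whose total
    delta matches ``observed_mass - base_mass`` within ``tol_ppm``.

    Generation order is deterministic (multisets in lexicographic mod-name
    order, placements in ascending site order); output is capped at ``cap``
    candidates with an explicit truncation flag.
    """
    mods = [
        m if isinstance(m, Modification) else MODIFICATIONS[m] for m in ptm_alphabet
    ]
    mods.sort(key=lambda m: m.name)
    base_mass = proteoform_neutral_mass(base)
    target = observed_mass - base_mass
    tol_da = tol_ppm * 1e-6 * observed_mass
    if target < -tol_da:
        raise MassDeficitError(
            f"observed mass {observed_mass:.5f} below base mass {base_mass:.5f}"
        )

    candidates: list[tuple[Proteoform, float]] = []
    truncated = False

    def emit(placements: tuple[tuple[int, str], ...], err: float) -> bool:
        nonlocal truncated
        if len(candidates) >= cap:
            truncated = True
            return False
        candidates.append((base.with_mods(placements), err))
        return True

    for k in range(0, max_mods + 1):
        for combo in itertools.combinations_with_replacement(mods, k):
            delta = sum(m.delta for m in combo)
            err = delta - target
            if abs(err) > tol_da:
                continue
            # group identical mods to avoid permuted duplicates
            groups: list[tuple[Modification, int]] = [
                (m, len(list(g))) for m, g in itertools.groupby(combo)
            ]
            per_group_sites = [
                (m, count, _allowed_sites(m, base, site_rules))
                for m, count in groups
            ]

            def place(gi: int, used: frozenset[int], acc: tuple) -> bool:
                if gi == len(per_group_sites):
                    return emit(acc, err)
                mod, count, sites = per_group_sites[gi]
                open_sites = [s for s in sites if s not in used]
                for chosen in itertools.combinations(open_sites, count):
                    if not place(
                        gi + 1,
                        used | frozenset(chosen),
                        acc + tuple((s, mod.name) for s in chosen),
                    ):
                        return False
                return True

            if not place(0, frozenset(), ()):
                break
        if truncated:
            break

    return CandidateSet(base, observed_mass, tuple(candidates), truncated)


def annotate_envelope(
    env: MassEnvelope,
    base: Proteoform,
    table: Sequence[DeltaExplanation],
    tol_da: float = 0.02,
    relative_to: str = "base",
) -> list[LabeledPeak]:
    """Label each envelope peak with its best mass-shift explanation.

    ``relative_to='base'`` measures every shift against the unmodified base
    mass; ``'previous'`` measures against the nearest lighter labeled peak
    (chained annotation).  Unexplained peaks carry their residual in Da.
    """
    if not env.peaks:
        raise ValueError("empty envelope")
    if relative_to not in ("base", "previous"):
        raise ValueError("relative_to must be 'base' or 'previous'")
    base_mass = proteoform_neutral_mass(base)
    out: list[LabeledPeak] = []
    reference = base_mass
    for mass, intensity in env.peaks:
        delta = mass - reference
        if abs(delta) <= tol_da:
            out.append(LabeledPeak(mass, intensity, "unmodified" if reference == base_mass else "isobaric", delta, delta))
        else:
            hits = explain_mass_shift(delta, table, tol_da)
            if hits:
                best = hits[0]
                out.append(LabeledPeak(mass, intensity, best.description, delta, best.error_da))
            else:
                out.append(LabeledPeak(mass, intensity, "unexplained", delta, None))
        if relative_to == "previous":
            reference = mass
    return out
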