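"""Exact monoisotopic mass chemistry.

Residue and modification masses, proteoform masses, m/z conversion, and
terminal fragment-ion ladders (a/b/c/y/z/z•).  All masses are monoisotopic
daltons computed from embedded elemental constants; average masses and
isotope envelopes are out of scope.

Site indexing convention: residue sites are 1-based on the processed
(initiator-Met-free) sequence; the protein/peptide N-terminus is site 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "PROTON",
    "WATER",
    "AMMONIA",
    "CO",
    "HYDROGEN",
    "RESIDUE_MASSES",
    "Modification",
    "MODIFICATIONS",
    "Proteoform",
    "FragmentIon",
    "N_TERMINAL_SERIES",
    "C_TERMINAL_SERIES",
    "UnknownResidueError",
    "UnknownModificationError",
    "InvalidProteoformError",
    "proteoform_neutral_mass",
    "mz_from_mass",
    "fragment_ladder",
    "parse_proteoform",
    "format_proteoform",
]

# Embedded monoisotopic constants (Da), documented to 6 decimals.
PROTON = 1.0072765
WATER = 18.010565
AMMONIA = 17.026549
CO = 27.994915
HYDROGEN = 1.007825

# Monoisotopic atomic masses used to derive residue/modification deltas.
_ATOM = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

_RESIDUE_FORMULA = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}


def _formula_mass(formula: str) -> float:
    mass = 0.0
    for sym, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not sym:
            continue
        mass += _ATOM[sym] * (int(count) if count else 1)
    return mass


#: One-letter amino acid -> monoisotopic residue mass (Da).
RESIDUE_MASSES: dict[str, float] = {
    aa: _formula_mass(f) for aa, f in _RESIDUE_FORMULA.items()
}

N_TERM = "N-TERM"
PROTEIN_N_TERM = "PROTEIN-N-TERM"


class UnknownResidueError(KeyError):
    """Raised for a residue letter missing from the residue table."""

    def __init__(self, residue: str):
        super().__init__(residue)
        self.residue = residue

    def __str__(self) -> str:  # pragma: no cover - message formatting
        return f"unknown residue letter: {self.residue!r}"


class UnknownModificationError(KeyError):
    """Raised for a modification name missing from the registry."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # pragma: no cover - message formatting
        return f"unknown modification name: {self.name!r}"


class InvalidProteoformError(ValueError):
    pass


@dataclass(frozen=True)
class Modification:
    """A named mass modification with its permitted attachment sites.

    ``allowed_sites`` holds one-letter residue codes and/or the tokens
    ``N-TERM`` (any peptide N-terminus) and ``PROTEIN-N-TERM``.
    """

    name: str
    delta: float
    allowed_sites: frozenset[str]
    composition: str = ""

    def allows_residue(self, residue: str) -> bool:
        return residue in self.allowed_sites

    def allows_n_term(self) -> bool:
        return N_TERM in self.allowed_sites or PROTEIN_N_TERM in self.allowed_sites


def _mod(name: str, composition: str, sites: Iterable[str]) -> Modification:
    return Modification(name, _formula_mass(composition), frozenset(sites), composition)


#: Built-in modification registry.  ``me1prop`` is the stacked
#: monomethyl + propionyl species produced by derivatizing a me1 lysine.
MODIFICATIONS: dict[str, Modification] = {
    m.name: m
    for m in (
        _mod("me1", "CH2", {"K", "R", PROTEIN_N_TERM}),
        _mod("me2", "C2H4", {"K", "R", PROTEIN_N_TERM}),
        _mod("me3", "C3H6", {"K", "R", PROTEIN_N_TERM}),
        _mod("ac", "C2H2O", {"K", PROTEIN_N_TERM}),
        _mod("ox", "O", {"M"}),
        _mod("prop", "C3H4O", {"K", N_TERM, PROTEIN_N_TERM}),
        _mod("me1prop", "C4H6O", {"K"}),
    )
}


def get_modification(name: str) -> Modification:
    try:
        return MODIFICATIONS[name]
    except KeyError:
        raise UnknownModificationError(name) from None


@dataclass(frozen=True)
class Proteoform:
    """A primary sequence plus a set of localized modifications.

    ``mods`` pairs a site (0 for the N-terminus, else a 1-based residue
    index) with a modification name.  At most one modification per site.
    """

    sequence: str
    mods: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mods", tuple(sorted(self.mods)))
        for aa in self.sequence:
            if aa not in RESIDUE_MASSES:
                raise UnknownResidueError(aa)
        seen: set[int] = set()
        for site, name in self.mods:
            mod = get_modification(name)
            if site in seen:
                raise InvalidProteoformError(f"duplicate modification site {site}")
            seen.add(site)
            if site == 0:
                if not mod.allows_n_term():
                    raise InvalidProteoformError(
                        f"modification {name!r} not allowed at the N-terminus"
                    )
            elif not (1 <= site <= len(self.sequence)):
                raise InvalidProteoformError(
                    f"modification site {site} outside sequence of length "
                    f"{len(self.sequence)}"
                )
            elif not mod.allows_residue(self.sequence[site - 1]):
                raise InvalidProteoformError(
                    f"modification {name!r} not allowed on residue "
                    f"{self.sequence[site - 1]}{site}"
                )

    @property
    def n_term_mod(self) -> str | None:
        for site, name in self.mods:
            if site == 0:
                return name
        return None

    def mod_at(self, site: int) -> str | None:
        for s, name in self.mods:
            if s == site:
                return name
        return None

    def with_mods(self, extra: Iterable[tuple[int, str]]) -> "Proteoform":
        return Proteoform(self.sequence, self.mods + tuple(extra))

    def notation(self) -> str:
        return format_proteoform(self)

    def __len__(self) -> int:
        return len(self.sequence)


N_TERMINAL_SERIES = ("a", "b", "c")
C_TERMINAL_SERIES = ("y", "z", "zdot")
ALL_SERIES = N_TERMINAL_SERIES + C_TERMINAL_SERIES


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical terminal fragment: series, 1-based residue count,
    neutral monoisotopic mass, and optional charge for m/z views."""

    series: str
    index: int
    neutral_mass: float
    charge: int | None = None

    @property
    def mz(self) -> float:
        if self.charge is None:
            raise ValueError("fragment has no charge assigned")
        return mz_from_mass(self.neutral_mass, self.charge)

    def label(self) -> str:
        base = "z•" if self.series == "zdot" else self.series
        return f"{base}{self.index}"


def proteoform_neutral_mass(p: Proteoform) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas."""
    mass = WATER
    for aa in p.sequence:
        try:
            mass += RESIDUE_MASSES[aa]
        except KeyError:
            raise UnknownResidueError(aa) from None
    for _site, name in p.mods:
        mass += get_modification(name).delta
    return mass


def mz_from_mass(neutral_mass: float, z: int) -> float:
    """m/z of the ``z``-fold protonated species."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON) / z


def fragment_ladder(
    p: Proteoform, series_set: Iterable[str] = ("c", "zdot")
) -> list[FragmentIon]:
    """Neutral-mass fragment ladders for the requested series.

    Indices run 1..n-1.  N-terminal series carry the N-terminal
    modification delta plus any residue modifications within the prefix;
    C-terminal series carry residue modifications within the suffix.
    """
    series_set = tuple(series_set)
    for s in series_set:
        if s not in ALL_SERIES:
            raise ValueError(f"unknown fragment series {s!r}")
    n = len(p.sequence)
    mod_delta = [0.0] * (n + 1)  # per residue site, index 0 = N-term
    for site, name in p.mods:
        mod_delta[site] += get_modification(name).delta

    # prefix[i] = residues 1..i + their mods + N-terminal mod
    prefix = [0.0] * (n + 1)
    acc = mod_delta[0]
    for i, aa in enumerate(p.sequence, start=1):
        acc += RESIDUE_MASSES[aa] + mod_delta[i]
        prefix[i] = acc
    total = prefix[n]

    out: list[FragmentIon] = []
    for series in series_set:
        for i in range(1, n):
            if series in N_TERMINAL_SERIES:
                b = prefix[i]
                if series == "b":
                    m = b
                elif series == "a":
                    m = b - CO
                else:  # c
                    m = b + AMMONIA
            else:
                y = total - prefix[n - i] + WATER
                if series == "y":
                    m = y
                elif series == "z":
                    m = y - AMMONIA
                else:  # zdot
                    m = y - AMMONIA + HYDROGEN
            out.append(FragmentIon(series, i, m))
    return out


# ---------------------------------------------------------------------------
# Proteoform text notation
#
# ``N-<mod><first-residue>`` prefix token plus ``<residue><pos><mod>``
# tokens, whitespace separated, e.g. ``N-acS K12ac K20me2``.  A proteoform
# with no modifications renders as ``unmodified``.

_NTERM_TOKEN = re.compile(r"^N-([a-z][a-z0-9]*)([A-Z])$")
_SITE_TOKEN = re.compile(r"^([A-Z])(\d+)([a-z][a-z0-9]*)$")


def format_proteoform(p: Proteoform) -> str:
    tokens = []
    for site, name in p.mods:
        if site == 0:
            tokens.append(f"N-{name}{p.sequence[0]}")
        else:
            tokens.append(f"{p.sequence[site - 1]}{site}{name}")
    return " ".join(tokens) if tokens else "unmodified"


def parse_proteoform(text: str, sequence: str) -> Proteoform:
    """Parse the modification notation against a known sequence.

    Round-trips with :func:`format_proteoform`.  Accepts ``unmodified``
    or an empty string for the bare sequence.
    """
    text = text.strip()
    if not text or text.lower() == "unmodified":
        return Proteoform(sequence)
    mods: list[tuple[int, str]] = []
    for token in text.split():
        m = _NTERM_TOKEN.match(token)
        if m:
            name, first = m.groups()
            if sequence and first != sequence[0]:
                raise InvalidProteoformError(
                    f"N-terminal token {token!r} names residue {first!r} but the "
                    f"sequence starts with {sequence[0]!r}"
                )
            mods.append((0, name))
            continue
        m = _SITE_TOKEN.match(token)
        if m:
            letter, pos_s, name = m.groups()
            pos = int(pos_s)
            if not (1 <= pos <= len(sequence)):
                raise InvalidProteoformError(
                    f"token {token!r}: position {pos} outside sequence"
                )
            if sequence[pos - 1] != letter:
                raise InvalidProteoformError(
                    f"token {token!r}: sequence has {sequence[pos - 1]!r} at "
                    f"position {pos}"
                )
            mods.append((pos, name))
            continue
        raise InvalidProteoformError(f"unparseable proteoform token {token!r}")
    return Proteoform(sequence, tuple(mods))
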