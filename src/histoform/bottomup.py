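"""In-silico propionylation, trypsin digestion, target lists, confirmation.

First-round propionylation derivatizes the protein N-terminus and every
free amine lysine; digestion then behaves Arg-C-like (K is blocked);
second-round propionylation labels the newly created peptide N-termini.
me1 lysines retain a labile proton and are propionylated (stacked
``me1prop``); ac/me2/me3 lysines are blocked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .fragmatch import (
    CID_SERIES,
    ScoreConfig,
    SpectrumPeaks,
    score_proteoform,
)
from .masscore import (
    Proteoform,
    format_proteoform,
    mz_from_mass,
    proteoform_neutral_mass,
)

__all__ = [
    "DigestRule",
    "DigestPeptide",
    "PeptideTarget",
    "ConfirmationRow",
    "propionylate",
    "digest",
    "build_target_list",
    "confirm_peptides",
    "PRECURSOR_TOL_DA",
]

PRECURSOR_TOL_DA = 0.01

# K states that block propionylation of the side chain
_BLOCKING_K_MODS = {"ac", "me2", "me3", "prop", "me1prop"}


@dataclass(frozen=True)
class DigestRule:
    """Cleavage specification; default is trypsin on propionylated histones
    (cleave after R, never before P, K blocked by derivatization)."""

    cleave_after: frozenset[str] = frozenset({"R"})
    no_cleave_before: frozenset[str] = frozenset({"P"})
    max_missed_cleavages: int = 1

    def __post_init__(self):
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with its 1-based inclusive span on the parent."""

    parent_id: str
    start: int
    end: int
    proteoform: Proteoform
    missed_cleavages: int

    @property
    def sequence(self) -> str:
        return self.proteoform.sequence


@dataclass(frozen=True)
class PeptideTarget:
    protein_id: str
    start: int
    end: int
    sequence: str
    mods: tuple[tuple[int, str], ...]
    charge: int
    mz: float

    @property
    def notation(self) -> str:
        return format_proteoform(Proteoform(self.sequence, self.mods))


@dataclass(frozen=True)
class ConfirmationRow:
    target: PeptideTarget
    spectrum_title: str
    confirmed: bool
    precursor_error_da: float | None
    sc_pct: float
    ic_pct: float
    ms: float


def propionylate(p: Proteoform, round: str = "first") -> Proteoform:
    """Add propionyl groups to free amines.

    ``first``: derivatize the N-terminus (unless already modified) and
    every K that is unmodified (-> prop) or me1 (-> me1prop).
    ``second``: derivatize only a free peptide N-terminus.
    """
    if round not in ("first", "second"):
        raise ValueError("round must be 'first' or 'second'")
    new_mods = list(p.mods)
    if p.mod_at(0) is None:
        new_mods.append((0, "prop"))
    if round == "first":
        for i, aa in enumerate(p.sequence, start=1):
            if aa != "K":
                continue
            existing = p.mod_at(i)
            if existing is None:
                new_mods.append((i, "prop"))
            elif existing == "me1":
                new_mods.remove((i, "me1"))
                new_mods.append((i, "me1prop"))
            # ac/me2/me3 block the side chain
    return Proteoform(p.sequence, tuple(new_mods))


def _cleavage_points(sequence: str, rule: DigestRule) -> list[int]:
    """Positions i such that the bond after residue i (1-based) is cut."""
    points = []
    n = len(sequence)
    for i in range(1, n):
        if sequence[i - 1] in rule.cleave_after and sequence[i] not in rule.no_cleave_before:
            points.append(i)
    return points


def digest(
    p: Proteoform,
    rule: DigestRule = DigestRule(),
    parent_id: str = "",
) -> list[DigestPeptide]:
    """Proteolytic products with 0..max missed cleavages.

    Modifications are carried over and re-indexed onto each peptide; the
    parent N-terminal modification stays with the first peptide only.
    At 0 missed cleavages the product spans tile the parent exactly.
    """
    n = len(p.sequence)
    cuts = [0] + _cleavage_points(p.sequence, rule) + [n]
    out: list[DigestPeptide] = []
    for a in range(len(cuts) - 1):
        for missed in range(rule.max_missed_cleavages + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            start, end = cuts[a] + 1, cuts[b]  # 1-based inclusive
            pep_mods = []
            for site, name in p.mods:
                if site == 0:
                    if start == 1:
                        pep_mods.append((0, name))
                elif start <= site <= end:
                    pep_mods.append((site - start + 1, name))
            out.append(
                DigestPeptide(
                    parent_id,
                    start,
                    end,
                    Proteoform(p.sequence[start - 1 : end], tuple(pep_mods)),
                    missed,
                )
            )
    out.sort(key=lambda d: (d.start, d.end))
    return out


def enumerate_site_options(
    site_options: Mapping[int, Sequence[str | None]],
) -> list[tuple[tuple[int, str], ...]]:
    """Cartesian product of per-site modification choices (None = free)."""
    sites = sorted(site_options)
    combos = []
    for choice in itertools.product(*(site_options[s] for s in sites)):
        combos.append(
            tuple((s, name) for s, name in zip(sites, choice) if name is not None)
        )
    return combos


def build_target_list(
    protein_id: str,
    sequence: str,
    mod_combinations: Iterable[Sequence[tuple[int, str]]] = ((),),
    charges: Sequence[int] = (2,),
    rule: DigestRule = DigestRule(),
    max_targets: int = 100_000,
) -> list[PeptideTarget]:
    """Full derivatization pipeline to an m/z target list.

    For each biological modification state of the parent: first-round
    propionylation, digestion, second-round propionylation of peptide
    N-termini, then expected m/z per charge.  Duplicate targets (same
    span, modifications, and charge) are emitted once.
    """
    if not charges:
        raise ValueError("at least one charge required")
    if any(z < 1 for z in charges):
        raise ValueError("charges must be >= 1")
    targets: dict[tuple, PeptideTarget] = {}
    for mods in mod_combinations:
        parent = Proteoform(sequence, tuple(mods))
        derivatized = propionylate(parent, "first")
        for pep in digest(derivatized, rule, protein_id):
            labeled = propionylate(pep.proteoform, "second")
            mass = proteoform_neutral_mass(labeled)
            for z in sorted(set(charges)):
                key = (pep.start, pep.end, labeled.mods, z)
                if key in targets:
                    continue
                targets[key] = PeptideTarget(
                    protein_id,
                    pep.start,
                    pep.end,
                    labeled.sequence,
                    labeled.mods,
                    z,
                    mz_from_mass(mass, z),
                )
                if len(targets) > max_targets:
                    raise ValueError("target list exceeds max_targets")
    return sorted(targets.values(), key=lambda t: (t.start, t.end, t.charge, t.notation))


def confirm_peptides(
    targets: Sequence[PeptideTarget],
    spectra: Sequence[SpectrumPeaks],
    precursor_tol_da: float = PRECURSOR_TOL_DA,
    frag_tol_ppm: float = 10.0,
) -> list[ConfirmationRow]:
    """Precursor-filtered CID confirmation of a target list.

    A spectrum is considered for a target when its precursor m/z lies
    within ``precursor_tol_da`` (and charges agree, when declared); the
    survivor is scored against the b/y ladder.  Targets with no matching
    spectrum are reported unconfirmed with zero scores.
    """
    rows: list[ConfirmationRow] = []
    for target in targets:
        best: ConfirmationRow | None = None
        for spectrum in spectra:
            if spectrum.precursor_mz is None:
                continue
            if (
                spectrum.precursor_charge is not None
                and spectrum.precursor_charge != target.charge
            ):
                continue
            err = spectrum.precursor_mz - target.mz
            if abs(err) > precursor_tol_da:
                continue
            result = score_proteoform(
                Proteoform(target.sequence, target.mods),
                spectrum,
                ScoreConfig(series_set=CID_SERIES, tol_ppm=frag_tol_ppm,
                            max_charge=max(1, target.charge - 1) if spectrum.mode == "mz" else 1),
            )
            row = ConfirmationRow(
                target, spectrum.title, True, err, result.sc_pct, result.ic_pct, result.ms
            )
            if best is None or row.ms > best.ms:
                best = row
        if best is None:
            best = ConfirmationRow(target, "", False, None, 0.0, 0.0, 0.0)
        rows.append(best)
    return rows
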