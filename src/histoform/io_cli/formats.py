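"""Readers and writers for FASTA, MGF, TSV peak lists, configs, and reports.

MGF dialect: BEGIN IONS / END IONS blocks, two-column peak lines,
``CHARGE=2+`` with trailing sign; unknown headers are ignored with a
warning.  TSV neutral-mass lists and envelopes are two tab-separated
columns with a mandatory header line.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Iterable, Sequence

import yaml
from Bio import SeqIO

from ..annotate_ms1 import MassEnvelope
from ..fragmatch import SpectrumPeaks

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
    "read_neutral_tsv",
    "write_neutral_tsv",
    "read_envelope_tsv",
    "write_envelope_tsv",
    "read_tags_tsv",
    "write_tags_tsv",
    "read_config",
    "config_hash",
    "write_report_csv",
    "write_truth_json",
]


class FormatError(ValueError):
    """Malformed input file; names the file and (when known) the line."""

    def __init__(self, path, message: str, line: int | None = None):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


# --- FASTA -----------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Multi-record FASTA (wrapped lines fine) as (id, sequence) pairs."""
    try:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    except Exception as exc:  # pragma: no cover - biopython error paths
        raise FormatError(path, f"cannot parse FASTA: {exc}") from exc
    if not records:
        raise FormatError(path, "no FASTA records found")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- MGF -------------------------------------------------------------------

_KNOWN_MGF_HEADERS = {"TITLE", "PEPMASS", "CHARGE", "RTINSECONDS", "SCANS"}


def read_mgf(path) -> list[SpectrumPeaks]:
    spectra: list[SpectrumPeaks] = []
    in_block = False
    title = ""
    pepmass: float | None = None
    charge: int | None = None
    values: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise FormatError(path, "nested BEGIN IONS", lineno)
                in_block = True
                title, pepmass, charge = "", None, None
                values, intensities = [], []
                continue
            if line == "END IONS":
                if not in_block:
                    raise FormatError(path, "END IONS without BEGIN IONS", lineno)
                spectra.append(
                    SpectrumPeaks(
                        tuple(values), tuple(intensities), "mz",
                        precursor_mz=pepmass, precursor_charge=charge, title=title,
                    )
                )
                in_block = False
                continue
            if not in_block:
                raise FormatError(path, f"unexpected content outside block: {line!r}", lineno)
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = value
                elif key == "PEPMASS":
                    try:
                        pepmass = float(value.split()[0])
                    except ValueError:
                        raise FormatError(path, f"bad PEPMASS {value!r}", lineno) from None
                elif key == "CHARGE":
                    v = value.strip()
                    sign = -1 if v.endswith("-") else 1
                    try:
                        charge = sign * int(v.rstrip("+-"))
                    except ValueError:
                        raise FormatError(path, f"bad CHARGE {value!r}", lineno) from None
                elif key not in _KNOWN_MGF_HEADERS:
                    warnings.warn(f"{path}:{lineno}: ignoring unknown MGF header {key}")
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(path, f"bad peak line {line!r}", lineno)
            try:
                values.append(float(parts[0]))
                intensities.append(float(parts[1]))
            except ValueError:
                raise FormatError(path, f"bad peak line {line!r}", lineno) from None
    if in_block:
        raise FormatError(path, "unterminated BEGIN IONS block")
    if not spectra:
        raise FormatError(path, "no spectra found")
    return spectra


def write_mgf(path, spectra: Iterable[SpectrumPeaks]) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            if s.title:
                fh.write(f"TITLE={s.title}\n")
            if s.precursor_mz is not None:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.precursor_charge is not None:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            for v, i in zip(s.values, s.intensities):
                fh.write(f"{v:.6f} {i:.4f}\n")
            fh.write("END IONS\n")


# --- TSV peak lists --------------------------------------------------------

def _read_two_column_tsv(path, expected_header: tuple[str, str]):
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise FormatError(path, "empty file", 1)
        cols = header.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise FormatError(path, f"expected 2-column header, got {header!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(path, f"expected 2 columns, got {line!r}", lineno)
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise FormatError(path, f"non-numeric row {line!r}", lineno) from None
    return rows


def read_neutral_tsv(path) -> SpectrumPeaks:
    """Deconvolved neutral fragment masses: ``neutral_mass<TAB>intensity``."""
    rows = _read_two_column_tsv(path, ("neutral_mass", "intensity"))
    return SpectrumPeaks(
        tuple(m for m, _ in rows), tuple(i for _, i in rows), "neutral"
    )


def write_neutral_tsv(path, peaks: SpectrumPeaks) -> None:
    with open(path, "w") as fh:
        fh.write("neutral_mass\tintensity\n")
        for v, i in zip(peaks.values, peaks.intensities):
            fh.write(f"{v:.6f}\t{i:.4f}\n")


def read_envelope_tsv(path) -> MassEnvelope:
    rows = _read_two_column_tsv(path, ("neutral_mass", "intensity"))
    try:
        return MassEnvelope(tuple(rows))
    except ValueError as exc:
        raise FormatError(path, str(exc)) from exc


def write_envelope_tsv(path, env: MassEnvelope) -> None:
    with open(path, "w") as fh:
        fh.write("neutral_mass\tintensity\n")
        for m, i in env.peaks:
            fh.write(f"{m:.6f}\t{i:.4f}\n")


# --- de novo tags ----------------------------------------------------------

def read_tags_tsv(path) -> list:
    from ..denovo_homology import SequenceTag

    tags = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "residues" not in header:
            raise FormatError(path, "missing 'residues' column", 1)
        idx = {name: i for i, name in enumerate(header)}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                tags.append(
                    SequenceTag(
                        parts[idx["residues"]],
                        float(parts[idx["prefix_mass"]]) if "prefix_mass" in idx else 0.0,
                        float(parts[idx["suffix_mass"]]) if "suffix_mass" in idx else 0.0,
                        parts[idx["series"]] if "series" in idx and len(parts) > idx["series"] else "",
                    )
                )
            except (IndexError, ValueError):
                raise FormatError(path, f"bad tag row {line!r}", lineno) from None
    if not tags:
        raise FormatError(path, "no tags found")
    return tags


def write_tags_tsv(path, tags: Sequence) -> None:
    with open(path, "w") as fh:
        fh.write("residues\tprefix_mass\tsuffix_mass\tseries\n")
        for t in tags:
            fh.write(f"{t.residues}\t{t.prefix_mass:.6f}\t{t.suffix_mass:.6f}\t{t.series}\n")


# --- config and reports ----------------------------------------------------

def read_config(path) -> dict:
    """JSON or YAML config, keyed by file extension."""
    text = Path(path).read_text()
    suffix = Path(path).suffix.lower()
    try:
        if suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise FormatError(path, f"cannot parse config: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(path, "config must be a mapping")
    return data


def config_hash(config: dict) -> str:
    """Short deterministic hash for report provenance."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_report_csv(
    path, rows: Sequence[dict[str, Any]], fieldnames: Sequence[str], config: dict | None = None
) -> None:
    """CSV report with an optional ``# config_hash=...`` provenance line."""
    with open(path, "w", newline="") as fh:
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        writer = csv.DictWriter(fh, fieldnames=list(fieldnames))
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def read_report_csv(path) -> list[dict]:
    with open(path, newline="") as fh:
        lines = [l for l in fh if not l.startswith("#")]
    return list(csv.DictReader(lines))


def write_truth_json(path, truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
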