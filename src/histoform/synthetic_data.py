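"""Seeded generators for envelopes, ECD/CID spectra, and isomer mixtures.

All randomness flows from one explicitly passed generator derived from the
mandatory config seed; identical seeds give identical outputs.  Intensity
draws are log-normal; noise peaks are uniform in mass over
[50 Da, precursor mass] with intensities scaled to 10% of the signal
median.  These are deliberately simple, documented models sufficient for
recovery and ranking tests — no physical cleavage-propensity modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotate_ms1 import MassEnvelope
from .fragmatch import ECD_SERIES, SpectrumPeaks
from .isoquant import IsomerGroup
from .masscore import Proteoform, fragment_ladder, proteoform_neutral_mass

__all__ = [
    "SimulationConfig",
    "simulate_ecd_spectrum",
    "simulate_envelope",
    "simulate_isomer_mixture",
]

NOISE_FLOOR_DA = 50.0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for spectrum simulation.  ``seed`` is mandatory."""

    seed: int
    ladder_completeness: float = 1.0
    ppm_jitter: float = 0.0
    noise_fraction: float = 0.0
    intensity_log_mean: float = np.log(100.0)
    intensity_log_sigma: float = 0.4
    series_set: tuple[str, ...] = ECD_SERIES
    mass_jitter_da: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.ladder_completeness <= 1.0):
            raise ValueError("ladder_completeness must lie in [0, 1]")
        if self.ppm_jitter < 0 or self.noise_fraction < 0 or self.mass_jitter_da < 0:
            raise ValueError("jitter and noise parameters must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise_peaks(
    rng: np.random.Generator,
    count: int,
    mass_hi: float,
    signal_median: float,
    sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    masses = rng.uniform(NOISE_FLOOR_DA, max(mass_hi, NOISE_FLOOR_DA + 1.0), count)
    intensities = rng.lognormal(np.log(max(signal_median * 0.1, 1e-9)), sigma, count)
    return masses, intensities


def simulate_ecd_spectrum(
    p: Proteoform,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SpectrumPeaks, dict]:
    """Partial fragment ladder with ppm jitter, log-normal intensities, and
    uniform noise peaks; returns the spectrum and the planted ground truth.
    """
    if rng is None:
        rng = cfg.rng()
    ladder = fragment_ladder(p, cfg.series_set)
    keep = rng.random(len(ladder)) < cfg.ladder_completeness
    sampled = [f for f, k in zip(ladder, keep) if k]
    masses = np.array([f.neutral_mass for f in sampled], dtype=float)
    if cfg.ppm_jitter > 0 and len(masses):
        masses = masses * (1.0 + rng.normal(0.0, cfg.ppm_jitter, len(masses)) * 1e-6)
    intensities = rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sigma, len(masses))

    precursor = proteoform_neutral_mass(p)
    n_noise = int(round(cfg.noise_fraction * max(len(sampled), 1))) if cfg.noise_fraction else 0
    if cfg.ladder_completeness == 0 and cfg.noise_fraction > 0:
        n_noise = max(n_noise, int(round(cfg.noise_fraction * len(ladder))))
    if n_noise:
        signal_median = float(np.median(intensities)) if len(intensities) else 1.0
        nm, ni = _noise_peaks(rng, n_noise, precursor, signal_median, cfg.intensity_log_sigma)
        masses = np.concatenate([masses, nm])
        intensities = np.concatenate([intensities, ni])

    spectrum = SpectrumPeaks(tuple(masses.tolist()), tuple(intensities.tolist()), "neutral")
    truth = {
        "proteoform": p.notation(),
        "sequence": p.sequence,
        "precursor_mass": precursor,
        "sampled_fragments": [f.label() for f in sampled],
        "n_noise": int(n_noise),
        "seed": cfg.seed,
    }
    return spectrum, truth


def simulate_envelope(
    proteoforms: Sequence[tuple[Proteoform, float]],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MassEnvelope, dict]:
    """Deconvolved MS1 envelope: one peak per distinct neutral mass, with
    isomers collapsing onto one peak with summed abundance."""
    if any(a < 0 for _, a in proteoforms):
        raise ValueError("abundances must be non-negative")
    if rng is None:
        rng = cfg.rng()
    peaks: dict[float, float] = {}
    truth_members: dict[float, list[str]] = {}
    for p, abundance in proteoforms:
        mass = round(proteoform_neutral_mass(p), 4)
        peaks[mass] = peaks.get(mass, 0.0) + abundance
        truth_members.setdefault(mass, []).append(p.notation())
    out = []
    for mass in sorted(peaks):
        jitter = rng.normal(0.0, cfg.mass_jitter_da) if cfg.mass_jitter_da > 0 else 0.0
        out.append((mass + jitter, peaks[mass]))
    env = MassEnvelope(tuple(sorted(out)))
    truth = {
        "peaks": [
            {"mass": m, "abundance": peaks[m], "members": truth_members[m]}
            for m in sorted(peaks)
        ],
        "seed": cfg.seed,
    }
    return env, truth


def simulate_isomer_mixture(
    group: IsomerGroup,
    fractions: Sequence[float],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SpectrumPeaks, dict]:
    """Chimeric fragment spectrum of co-isolated positional isomers.

    Per-isomer ladders are sampled and scaled by their fraction; fragments
    shared between isomers (identical theoretical mass) add coherently.
    Fractions must sum to 1 within 1e-9.
    """
    if len(fractions) != len(group.members):
        raise ValueError("one fraction per group member required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)!r}")
    if rng is None:
        rng = cfg.rng()

    accumulated: dict[float, float] = {}
    for member, fraction in zip(group.members, fractions):
        ladder = fragment_ladder(member, cfg.series_set)
        keep = rng.random(len(ladder)) < cfg.ladder_completeness
        intensities = rng.lognormal(
            cfg.intensity_log_mean, cfg.intensity_log_sigma, len(ladder)
        )
        if fraction == 0:
            continue
        for frag, k, inten in zip(ladder, keep, intensities):
            if not k:
                continue
            key = round(frag.neutral_mass, 6)
            accumulated[key] = accumulated.get(key, 0.0) + fraction * inten

    masses = np.array(sorted(accumulated), dtype=float)
    intensities = np.array([accumulated[m] for m in sorted(accumulated)])
    if cfg.ppm_jitter > 0 and len(masses):
        masses = masses * (1.0 + rng.normal(0.0, cfg.ppm_jitter, len(masses)) * 1e-6)

    precursor = proteoform_neutral_mass(group.members[0])
    n_noise = int(round(cfg.noise_fraction * len(masses))) if cfg.noise_fraction else 0
    if n_noise:
        signal_median = float(np.median(intensities)) if len(intensities) else 1.0
        nm, ni = _noise_peaks(rng, n_noise, precursor, signal_median, cfg.intensity_log_sigma)
        masses = np.concatenate([masses, nm])
        intensities = np.concatenate([intensities, ni])

    spectrum = SpectrumPeaks(tuple(masses.tolist()), tuple(intensities.tolist()), "neutral")
    truth = {
        "members": [m.notation() for m in group.members],
        "fractions": list(map(float, fractions)),
        "seed": cfg.seed,
        "n_noise": int(n_noise),
    }
    return spectrum, truth
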