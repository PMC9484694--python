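"""Uncharged-mass reconstruction from a five-peak ESI charge ladder.

An electrosprayed species of neutral mass M appears as [M+zH]z+ at
several consecutive charges; the spacing of adjacent peaks determines
the charge, and each peak then gives an independent estimate of M. This
module implements the five-peak variant of that procedure (after the
ESIprot approach): the lowest charge is inferred from the four adjacent
pairs, charges are reassigned from it, and the five per-peak masses are
averaged.

The working formulas subtract a bare ``1`` per proton (z1 = (m2-1)/
(m2-m1); mass = z*m - z), which keeps results on the same scale as the
original procedure. Pass ``physical_proton=True`` to use 1.00728 Da
instead; the reconstructed mean then loses its small systematic offset
of mean(z) x 0.00728 Da.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .chem import PROTON_MASS
from .ms_io import InstrumentProfile

__all__ = ["ChargeLadder", "DeconvResult", "infer_lowest_charge",
           "reconstruct_mass", "deconvolve", "select_ladder"]

LADDER_SIZE = 5


@dataclass(frozen=True)
class ChargeLadder:
    """Five consecutively charged m/z values of one species, ascending."""

    mz_values: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        mz = tuple(float(v) for v in self.mz_values)
        if len(mz) != LADDER_SIZE:
            raise ValueError(f"a charge ladder has exactly {LADDER_SIZE} peaks")
        if any(v <= 0 for v in mz):
            raise ValueError("m/z values must be positive")
        if any(b <= a for a, b in zip(mz, mz[1:])):
            raise ValueError("m/z values must be strictly increasing")
        object.__setattr__(self, "mz_values", mz)


@dataclass(frozen=True)
class DeconvResult:
    """Charges, per-peak masses, and uncertainty for one ladder.

    ``reported_sd`` is the larger of the sample standard deviation and
    the instrument resolution floor sigma x z1 (zero floor when no
    instrument was supplied).
    """

    charges: tuple[int, int, int, int, int]  # descending, aligned to mz
    per_peak_masses: tuple[float, ...]
    mean_mass: float
    sample_sd: float
    reported_sd: float
    resolution_floor: float

    def to_dict(self) -> dict:
        return asdict(self)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def infer_lowest_charge(
    ladder: ChargeLadder, proton: float = 1.0
) -> int:
    """Infer the charge of the highest-m/z peak (the lowest charge, z5).

    Each adjacent pair (m_i, m_{i+1}) gives a charge estimate for peak i,
    z_i = (m_{i+1} - proton) / (m_{i+1} - m_i); subtracting peak i's
    proton excess over peak 5 converts it to a z5 estimate. The four
    estimates are averaged and rounded to the nearest integer (half away
    from zero).
    """
    mz = ladder.mz_values
    estimates = []
    for i in range(4):
        spacing = mz[i + 1] - mz[i]
        z_i = (mz[i + 1] - proton) / spacing
        estimates.append(z_i - (4 - i))  # peak i carries 4-i protons more than m5
    z5 = _round_half_away(float(np.mean(estimates)))
    if z5 < 1:
        raise ValueError(
            f"inferred lowest charge {z5} is non-physical; "
            "peaks do not form a consecutive charge ladder")
    return z5


def reconstruct_mass(
    ladder: ChargeLadder, z5: int, physical_proton: bool = False
) -> DeconvResult:
    """Reconstruct the uncharged mass given the lowest charge.

    Charges z5+4 .. z5 are assigned against ascending m/z; each peak
    contributes mass z*m - z*proton; the mean and sample standard
    deviation over the five are reported. No resolution floor is applied
    here (see :func:`deconvolve`).
    """
    if z5 < 1:
        raise ValueError("z5 must be >= 1")
    proton = PROTON_MASS if physical_proton else 1.0
    mz = np.asarray(ladder.mz_values)
    charges = np.arange(z5 + 4, z5 - 1, -1)  # descending with ascending m/z
    masses = charges * mz - charges * proton
    mean = float(np.mean(masses))
    sd = float(np.std(masses, ddof=1))
    return DeconvResult(
        charges=tuple(int(z) for z in charges),
        per_peak_masses=tuple(float(m) for m in masses),
        mean_mass=mean,
        sample_sd=sd,
        reported_sd=sd,
        resolution_floor=0.0,
    )


def deconvolve(
    ladder: ChargeLadder,
    instrument: InstrumentProfile | None = None,
    physical_proton: bool = False,
) -> DeconvResult:
    """Full ladder deconvolution: infer z5, reconstruct, apply the floor.

    The reported uncertainty is never smaller than the instrument
    resolution floor sigma x z1 (the single-charge peak width scaled by
    the largest observed charge).
    """
    proton = PROTON_MASS if physical_proton else 1.0
    z5 = infer_lowest_charge(ladder, proton=proton)
    result = reconstruct_mass(ladder, z5, physical_proton=physical_proton)
    floor = instrument.sigma * result.charges[0] if instrument else 0.0
    return DeconvResult(
        charges=result.charges,
        per_peak_masses=result.per_peak_masses,
        mean_mass=result.mean_mass,
        sample_sd=result.sample_sd,
        reported_sd=max(result.sample_sd, floor),
        resolution_floor=floor,
    )


def select_ladder(
    mz: np.ndarray,
    intensity: np.ndarray,
    consistency_tol: float = 0.25,
) -> ChargeLadder:
    """Heuristically pick five intense peaks forming one charge ladder.

    Beyond the core procedure (which takes the five m/z values as
    given): candidate windows of five peaks, ranked by total intensity,
    are accepted when their four pairwise charge estimates agree with a
    consecutive-ladder assignment within ``consistency_tol`` charges.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    if len(mz) < LADDER_SIZE:
        raise ValueError("need at least five peaks to select a ladder")

    best, best_score = None, -np.inf
    for start in range(len(mz) - LADDER_SIZE + 1):
        window = mz[start:start + LADDER_SIZE]
        if np.any(np.diff(window) <= 0):
            continue
        ests = [(window[i + 1] - 1.0) / (window[i + 1] - window[i]) - (4 - i)
                for i in range(4)]
        if max(ests) - min(ests) > 2 * consistency_tol:
            continue
        z5 = float(np.mean(ests))
        if z5 < 0.5 or abs(z5 - round(z5)) > consistency_tol:
            continue
        score = float(intensity[start:start + LADDER_SIZE].sum())
        if score > best_score:
            best, best_score = window, score
    if best is None:
        raise ValueError("no five-peak window is consistent with one ladder")
    return ChargeLadder(tuple(best))
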