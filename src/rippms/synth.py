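"""Ground-truth synthetic LC-MS and MS/MS data generation.

Emulates the statistical structure of centroided single-quadrupole /
Q-TOF runs of large (2-20 kDa) peptide fusions: each species elutes as
a skew-normal peak over a 1-6 min window and appears at every charge
state its mass supports inside the scan range, with intensities spread
over a discretized-Gaussian charge envelope; Poisson-count noise peaks
with exponential intensities are scattered uniformly over the scan
range. One centroid is written per charge state at the average-mass
m/z (no isotope fine structure) — what a unit-resolution centroid
stream supports; an optional isotope-cluster mode adds 1.00235/z-spaced
satellites for high-resolution realism.

Every generator is deterministic given its seed, and returns the ground
truth needed to score downstream recovery.
"""

from __future__ import annotations

import base64
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree
from scipy.stats import skewnorm

from .chem import (
    DEFAULT_MODIFICATIONS,
    ModificationDelta,
    ModificationState,
    charges_in_range,
    enumerate_states,
    mz_for_charge,
)
from .ms_io import QQQ, Chromatogram, InstrumentProfile, SignalTable
from .msms import PeptideStructure, Spectrum, hypothetical_ions

__all__ = [
    "SpeciesSpec",
    "RunSpec",
    "simulate_run",
    "simulate_msms",
    "write_mzxml",
    "standard_two_state_run",
    "DEFAULT_FUSION_PEPTIDE",
]

# A realistic 72-residue stand-in for a tagged RiPP precursor fusion
# (~7.9 kDa average), synthetic sequence with a Ser/Thr-rich C-terminal
# core as a dehydration substrate.
DEFAULT_FUSION_PEPTIDE = (
    "MGSSHHHHHHGSDSEVNQEAKPEVKPEVKPETHINLKVSDGSSEIFFKIKKTT"
    "GLSKSELMAQTSISTVSCC"
)


@dataclass(frozen=True)
class SpeciesSpec:
    """One co-eluting species: a modification state with its elution
    profile and charge envelope.

    ``abundance`` is the integrated ECC area the species should produce
    (intensity x minutes). ``elution`` is (apex location min, width min,
    skew) of a skew-normal profile. ``charge_envelope`` is (center
    charge, spread) of the Gaussian weighting across charge states.
    """

    state: ModificationState
    abundance: float
    elution: tuple[float, float, float]
    charge_envelope: tuple[float, float]

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.elution[1] <= 0:
            raise ValueError("elution width must be positive")
        if self.charge_envelope[1] <= 0:
            raise ValueError("charge envelope spread must be positive")


@dataclass(frozen=True)
class RunSpec:
    """A full synthetic LC-MS run: species, instrument, window, noise.

    ``noise`` is (mean noise peaks per scan, mean noise intensity);
    counts are Poisson, m/z uniform over the scan range, intensities
    exponential. ``seed`` is mandatory — runs are reproducible by
    construction.
    """

    species: tuple[SpeciesSpec, ...]
    instrument: InstrumentProfile = QQQ
    rt_window: tuple[float, float] = (1.0, 6.0)
    noise: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    emit_floor: float = 1.0
    isotope_mode: bool = False

    def __post_init__(self) -> None:
        if self.rt_window[0] >= self.rt_window[1]:
            raise ValueError("rt_window must be ordered (start, end)")


def _scan_grid(spec: RunSpec) -> np.ndarray:
    step = spec.instrument.scan_interval / 60.0
    n = int(math.floor((spec.rt_window[1] - spec.rt_window[0]) / step)) + 1
    return spec.rt_window[0] + step * np.arange(n)


def simulate_run(spec: RunSpec) -> tuple[SignalTable, dict]:
    """Generate a centroided MS1 run and its ground truth.

    Peak intensity for species s, charge z, scan t is
    ``abundance_s x w_z x skewnorm_pdf(t)`` with envelope weights w_z
    normalized to sum 1 over the charges in range, so the integrated
    compound signal equals the specified abundance. Peaks below
    ``emit_floor`` are not written (detector threshold).
    """
    rng = np.random.default_rng(spec.seed)
    grid = _scan_grid(spec)
    mz_lo, mz_hi = spec.instrument.scan_mz_range

    rows_rt, rows_mz, rows_int = [], [], []
    truth_species = []
    for sp in spec.species:
        mass = sp.state.expected_mass
        charges = np.array(charges_in_range(mass, mz_lo, mz_hi))
        if len(charges) == 0:
            raise ValueError(
                f"species mass {mass:.1f} Da has no charge state inside "
                f"the {spec.instrument.name} scan range {mz_lo}-{mz_hi}")
        center, spread = sp.charge_envelope
        weights = np.exp(-0.5 * ((charges - center) / spread) ** 2)
        weights /= weights.sum()
        apex, width, skew = sp.elution
        profile = skewnorm.pdf(grid, skew, loc=apex, scale=width)
        mzs = np.array([mz_for_charge(mass, int(z)) for z in charges])

        # intensity matrix: scans x charges
        inten = sp.abundance * np.outer(profile, weights)
        scan_idx, charge_idx = np.nonzero(inten >= spec.emit_floor)
        rows_rt.append(grid[scan_idx])
        rows_mz.append(mzs[charge_idx])
        rows_int.append(inten[scan_idx, charge_idx])
        if spec.isotope_mode:
            for offset in (-1, 1, 2):
                sat = inten[scan_idx, charge_idx] * 0.5 ** abs(offset)
                keep = sat >= spec.emit_floor
                rows_rt.append(grid[scan_idx][keep])
                rows_mz.append(mzs[charge_idx][keep]
                               + offset * 1.00235 / charges[charge_idx][keep])
                rows_int.append(sat[keep])
        truth_species.append({
            "name": sp.state.name,
            "label": sp.state.label,
            "mass": mass,
            "abundance": sp.abundance,
            "apex_rt": apex,
            "charges": [int(z) for z in charges],
        })

    noise_rate, noise_scale = spec.noise
    if noise_rate > 0 and noise_scale > 0:
        counts = rng.poisson(noise_rate, size=len(grid))
        total = int(counts.sum())
        rows_rt.append(np.repeat(grid, counts))
        rows_mz.append(rng.uniform(mz_lo, mz_hi, size=total))
        rows_int.append(rng.exponential(noise_scale, size=total))

    frame = pd.DataFrame({
        "rt": np.concatenate(rows_rt) if rows_rt else np.array([]),
        "mz": np.concatenate(rows_mz) if rows_mz else np.array([]),
        "intensity": np.concatenate(rows_int) if rows_int else np.array([]),
    })
    table = SignalTable(frame, source=f"synthetic(seed={spec.seed})",
                        instrument=spec.instrument)

    total_abundance = sum(sp.abundance for sp in spec.species)
    modified_abundance = sum(sp.abundance for sp in spec.species
                             if sp.state.label == "modified")
    truth = {
        "seed": spec.seed,
        "species": truth_species,
        "total_abundance": total_abundance,
        "fraction_modified": modified_abundance / total_abundance,
    }
    return table, truth


def simulate_msms(
    structure: PeptideStructure,
    efficiency: float = 0.7,
    noise_peaks: int = 300,
    noise_intensity: float = 20.0,
    intensity_median: float = 5000.0,
    intensity_sigma: float = 0.5,
    mz_jitter: float = 0.005,
    seed: int = 0,
    max_charge: int = 3,
) -> tuple[Spectrum, dict]:
    """Generate an MS/MS spectrum from a structure's hypothetical ions.

    Each hypothetical ion is emitted with probability ``efficiency`` at
    a log-normal intensity (median ``intensity_median``, log-scale sd
    ``intensity_sigma``), its m/z jittered by N(0, mz_jitter); noise
    peaks are uniform over the ion m/z range with exponential
    intensities. Defaults put fragment peaks two orders of magnitude
    above the noise floor — the regime targeted fragmentation of an
    abundant purified peptide produces. Ground truth lists the injected
    ions.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ions = hypothetical_ions(structure, max_charge=max_charge)
    emitted = [ion for ion in ions if rng.random() < efficiency]

    mzs, intens = [], []
    for ion in emitted:
        mzs.append(ion.mz + rng.normal(0.0, mz_jitter))
        intens.append(rng.lognormal(mean=math.log(intensity_median),
                                    sigma=intensity_sigma))
    if noise_peaks > 0 and ions:
        lo = min(ion.mz for ion in ions) * 0.8
        hi = max(ion.mz for ion in ions) * 1.1
        mzs.extend(rng.uniform(lo, hi, size=noise_peaks))
        intens.extend(rng.exponential(noise_intensity, size=noise_peaks))

    spectrum = Spectrum(np.array(mzs) if mzs else np.empty(0),
                        np.array(intens) if intens else np.empty(0),
                        meta=f"synthetic(seed={seed})")
    truth = {
        "seed": seed,
        "injected": emitted,
        "n_hypothetical": len(ions),
        "n_injected": len(emitted),
        "n_noise": int(noise_peaks),
    }
    return spectrum, truth


MZXML_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"


def write_mzxml(table: SignalTable, path: str | os.PathLike) -> None:
    """Write a SignalTable as minimal centroided MS1 mzXML.

    Peaks are base64-encoded network-order float64 (m/z, intensity)
    pairs, one scan per distinct retention time; readable back with
    :func:`rippms.ms_io.read_mzxml` with exact record recovery.
    """
    root = etree.Element(f"{{{MZXML_NS}}}mzXML", nsmap={None: MZXML_NS})
    grouped = list(table.frame.groupby("rt", sort=True))
    run = etree.SubElement(root, f"{{{MZXML_NS}}}msRun",
                           scanCount=str(len(grouped)))
    for num, (rt, scan) in enumerate(grouped, start=1):
        el = etree.SubElement(
            run, f"{{{MZXML_NS}}}scan",
            num=str(num), msLevel="1", centroided="1",
            peaksCount=str(len(scan)),
            retentionTime=f"PT{float(rt) * 60.0:.6f}S",
        )
        interleaved = np.empty(2 * len(scan))
        interleaved[0::2] = scan["mz"].to_numpy()
        interleaved[1::2] = scan["intensity"].to_numpy()
        payload = base64.b64encode(interleaved.astype(">f8").tobytes())
        peaks = etree.SubElement(
            el, f"{{{MZXML_NS}}}peaks",
            precision="64", byteOrder="network", contentType="m/z-int",
            compressionType="none", compressedLen="0",
        )
        peaks.text = payload.decode("ascii")
    etree.ElementTree(root).write(
        os.fspath(path), xml_declaration=True, encoding="ISO-8859-1",
        pretty_print=True)


def standard_two_state_run(
    fraction_modified: float,
    seed: int,
    peptide: str = DEFAULT_FUSION_PEPTIDE,
    delta: ModificationDelta = DEFAULT_MODIFICATIONS["dehydration"],
    instrument: InstrumentProfile = QQQ,
    total_abundance: float = 2.0e7,
    apex_rt: float = 3.2,
    elution_width: float = 0.08,
    elution_skew: float = 1.0,
    noise: tuple[float, float] = (5.0, 2.0e4),
) -> RunSpec:
    """Build the reference two-species run used throughout testing.

    An unmodified and a singly dehydrated fusion peptide co-elute at
    ``apex_rt``; abundances are split so the true fraction modified is
    ``fraction_modified``. Default noise gives a signal-to-noise ratio
    well above 20 at the apex.
    """
    if not 0.0 <= fraction_modified <= 1.0:
        raise ValueError("fraction_modified must be in [0, 1]")
    states = enumerate_states(peptide, [delta])
    unmod = next(s for s in states if s.label == "unmodified")
    mod = next(s for s in states if s.label == "modified")
    charges = charges_in_range(unmod.expected_mass,
                               *instrument.scan_mz_range)
    center = float(np.mean(charges))
    species = []
    for state, frac in ((unmod, 1.0 - fraction_modified),
                        (mod, fraction_modified)):
        if frac <= 0:
            continue
        species.append(SpeciesSpec(
            state=state,
            abundance=frac * total_abundance,
            elution=(apex_rt, elution_width, elution_skew),
            charge_envelope=(center, 4.0),
        ))
    return RunSpec(species=tuple(species), instrument=instrument,
                   rt_window=(1.0, 6.0), noise=noise, seed=seed)
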