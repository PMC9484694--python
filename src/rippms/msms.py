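"""MS/MS spectrum preprocessing and b/y hypothetical-ion annotation.

The annotation strategy avoids spectrum deconvolution: hypothetical
b/y fragment and parent masses of a (modified, possibly macrocyclic)
peptide are projected to the 1+, 2+ and 3+ charge states and matched
directly against the centroided spectrum after two cleanup steps — an
intensity ceiling relative to the spectrum mean, and sliced background
removal with a local signal-to-noise threshold.

Monoisotopic masses throughout. Modification deltas are localized to
residues, so a fragment carries exactly the deltas of the residues it
retains. Backbone cleavage sites strictly inside a crosslinked (ring)
span produce no fragments: both product pieces would stay tethered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    PROTON_MASS,
    WATER_MONOISOTOPIC,
    residue_mass,
    validate_sequence,
)

__all__ = [
    "Spectrum",
    "PeptideStructure",
    "AnnotationParams",
    "FragmentIon",
    "AnnotationResult",
    "cap_intensities",
    "remove_background",
    "hypothetical_ions",
    "match_ions",
    "read_spectrum",
]


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    meta: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if (self.mz <= 0).any():
            raise ValueError("m/z values must be positive")
        if (self.intensity < 0).any():
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class PeptideStructure:
    """A peptide with residue-localized monoisotopic deltas and rings.

    ``residue_deltas`` maps 1-based positions to signed monoisotopic
    shifts. ``crosslinks`` are (start, end) residue spans (1-based,
    inclusive) joined by a ring; spans may nest but not partially
    overlap.
    """

    sequence: str
    residue_deltas: Mapping[int, float] = field(default_factory=dict)
    crosslinks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        L = len(self.sequence)
        for pos in self.residue_deltas:
            if not 1 <= pos <= L:
                raise ValueError(f"delta position {pos} outside 1..{L}")
        spans = tuple(tuple(span) for span in self.crosslinks)
        for s, e in spans:
            if not (1 <= s < e <= L):
                raise ValueError(f"invalid crosslink span ({s}, {e})")
        for (s1, e1) in spans:
            for (s2, e2) in spans:
                if s1 < s2 <= e1 < e2:
                    raise ValueError(
                        f"crosslinks ({s1},{e1}) and ({s2},{e2}) "
                        "partially overlap")
        object.__setattr__(self, "crosslinks", spans)
        object.__setattr__(self, "residue_deltas", dict(self.residue_deltas))

    def open_sites(self) -> list[int]:
        """Cleavage sites (between residue k and k+1) outside all rings."""
        sites = []
        for k in range(1, len(self.sequence)):
            if not any(s <= k < e for s, e in self.crosslinks):
                sites.append(k)
        return sites


@dataclass(frozen=True)
class AnnotationParams:
    """User-facing knobs of the annotation procedure."""

    ceiling_multiplier: float = 5.0
    n_slices: int = 10
    snr_threshold: float = 2.0
    match_tolerance: float = 0.05
    max_charge: int = 3

    def __post_init__(self) -> None:
        if min(self.ceiling_multiplier, self.snr_threshold) < 0:
            raise ValueError("multipliers must be non-negative")
        if self.n_slices < 1 or self.max_charge < 1:
            raise ValueError("n_slices and max_charge must be >= 1")


@dataclass(frozen=True)
class FragmentIon:
    """A hypothetical b/y/parent ion at one charge state."""

    series: str  # "b", "y", or "parent"
    index: int   # residues retained
    charge: int
    formula_mass: float  # neutral-fragment formula mass, Da
    mz: float

    @property
    def name(self) -> str:
        if self.series == "parent":
            return f"[M+{self.charge}H]{self.charge}+"
        return f"{self.series}{self.index}({self.charge}+)"


@dataclass
class AnnotationResult:
    """Matched ions and cleavage-site coverage for one spectrum."""

    matches: list[tuple[FragmentIon, float, float]]  # ion, peak mz, intensity
    n_matched: int
    coverage: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"ion": ion.name, "series": ion.series, "index": ion.index,
              "charge": ion.charge, "mz_expected": ion.mz,
              "mz_observed": mz, "intensity": inten,
              "error_mz": mz - ion.mz}
             for ion, mz, inten in self.matches]
        )


def cap_intensities(spec: Spectrum, ceiling_multiplier: float) -> Spectrum:
    """Clip intensities at multiplier x mean intensity.

    Tames dominant peaks (often precursor or immonium signals) so the
    background statistics of the removal step are not skewed by them.
    """
    if len(spec) == 0:
        raise ValueError("empty spectrum")
    ceiling = ceiling_multiplier * float(spec.intensity.mean())
    return Spectrum(spec.mz.copy(), np.minimum(spec.intensity, ceiling),
                    spec.precursor_mz, spec.meta)


def remove_background(
    spec: Spectrum, n_slices: int, snr_threshold: float
) -> Spectrum:
    """Remove peaks below a sliced local signal-to-noise threshold.

    The m/z range is cut into ``n_slices`` equal windows; each slice's
    threshold is the mean intensity over the slice and its existing
    flanking slices (no wraparound), times ``snr_threshold``. Peaks
    strictly below their slice threshold are removed.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if len(spec) == 0:
        raise ValueError("empty spectrum")
    lo, hi = float(spec.mz.min()), float(spec.mz.max())
    width = (hi - lo) / n_slices if hi > lo else 1.0
    idx = np.minimum(((spec.mz - lo) / width).astype(int), n_slices - 1)

    keep = np.zeros(len(spec), dtype=bool)
    for i in range(n_slices):
        in_slice = idx == i
        if not in_slice.any():
            continue
        neighborhood = (idx >= i - 1) & (idx <= i + 1)
        threshold = snr_threshold * float(spec.intensity[neighborhood].mean())
        keep |= in_slice & (spec.intensity >= threshold)
    return Spectrum(spec.mz[keep], spec.intensity[keep],
                    spec.precursor_mz, spec.meta)


def hypothetical_ions(
    structure: PeptideStructure, max_charge: int = 3
) -> list[FragmentIon]:
    """Enumerate b/y and parent ions of a structure at charges 1..max.

    b_k is the N-terminal piece retaining k residues (formula mass =
    residue sum plus retained deltas); y_k the C-terminal piece plus one
    water. The parent is the full peptide plus water. Sites inside
    crosslink spans are skipped. m/z = (formula + z x 1.00728) / z.
    """
    seq = structure.sequence
    L = len(seq)
    masses = np.array([residue_mass(ch, "monoisotopic") for ch in seq])
    for pos, delta in structure.residue_deltas.items():
        masses[pos - 1] += delta
    prefix = np.concatenate([[0.0], np.cumsum(masses)])

    ions = []
    parent_mass = float(prefix[L]) + WATER_MONOISOTOPIC
    open_sites = set(structure.open_sites())
    for k in range(1, L):
        if k not in open_sites:
            continue
        b_mass = float(prefix[k])
        y_mass = float(prefix[L] - prefix[k]) + WATER_MONOISOTOPIC
        for z in range(1, max_charge + 1):
            ions.append(FragmentIon("b", k, z, b_mass,
                                    (b_mass + z * PROTON_MASS) / z))
            ions.append(FragmentIon("y", L - k, z, y_mass,
                                    (y_mass + z * PROTON_MASS) / z))
    for z in range(1, max_charge + 1):
        ions.append(FragmentIon("parent", L, z, parent_mass,
                                (parent_mass + z * PROTON_MASS) / z))
    return ions


def match_ions(
    spec: Spectrum,
    ions: Sequence[FragmentIon],
    match_tolerance: float,
) -> AnnotationResult:
    """Match hypothetical ions to a preprocessed spectrum.

    Each ion takes the nearest peak within ``match_tolerance`` m/z
    (ties resolved toward the lower-m/z peak); one peak may support
    several ions. Coverage is the fraction of cleavage sites having at
    least one hypothetical ion that are supported by a match.
    """
    matches = []
    supported: set[tuple[str, int]] = set()
    if len(spec):
        for ion in ions:
            j = int(np.searchsorted(spec.mz, ion.mz))
            candidates = [c for c in (j - 1, j) if 0 <= c < len(spec)]
            best = None
            for c in candidates:
                d = abs(spec.mz[c] - ion.mz)
                if d <= match_tolerance and (best is None or d < best[1]):
                    best = (c, d)
            if best is not None:
                c = best[0]
                matches.append((ion, float(spec.mz[c]),
                                float(spec.intensity[c])))
                supported.add((ion.series, ion.index))

    L = _parent_len(ions)
    sites_with_ions = (
        {ion.index for ion in ions if ion.series == "b"}
        | {L - ion.index for ion in ions if ion.series == "y"}
    )
    covered = (
        {idx for series, idx in supported if series == "b"}
        | {L - idx for series, idx in supported if series == "y"}
    )
    coverage = (len(covered & sites_with_ions) / len(sites_with_ions)
                if sites_with_ions else 0.0)
    return AnnotationResult(matches=matches, n_matched=len(matches),
                            coverage=coverage)


def _parent_len(ions: Sequence[FragmentIon]) -> int:
    for ion in ions:
        if ion.series == "parent":
            return ion.index
    raise ValueError("ion list lacks a parent ion; cannot infer length")


def read_spectrum(path: str) -> Spectrum:
    """Read a spectrum from two-column TSV (mz, intensity) or MGF."""
    if path.lower().endswith(".mgf"):
        from pyteomics import mgf

        with mgf.read(path) as reader:
            entries = list(reader)
        if len(entries) != 1:
            raise ValueError(
                f"expected a single-spectrum MGF, found {len(entries)}")
        entry = entries[0]
        pep = entry["params"].get("pepmass")
        precursor = float(pep[0]) if pep else None
        return Spectrum(entry["m/z array"], entry["intensity array"],
                        precursor_mz=precursor, meta=path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame.columns = [c.lower() for c in frame.columns]
    return Spectrum(frame.iloc[:, 0].to_numpy(),
                    frame.iloc[:, 1].to_numpy(), meta=path)
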