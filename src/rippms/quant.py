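"""Fraction-modified quantification from extracted compound chromatograms.

For each candidate modification state of a peptide, every charge state
inside the scan range is extracted as a narrow-window EIC; the EICs are
summed pointwise into an extracted compound chromatogram (ECC); the ECC
peak is fit with a skew-normal (skewed Gaussian) plus a flat baseline;
and the fitted peak is accepted only if it carries multi-charge-state
evidence and a clean chromatographic shape. The fraction modified of an
extract is the valid modified-state area over the total valid peptide
area (unmodified + partial + modified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.stats import skewnorm

from .chem import (
    ModificationDelta,
    ModificationState,
    charges_in_range,
    enumerate_states,
    mz_for_charge,
)
from .ms_io import Chromatogram, InstrumentProfile, SignalTable

__all__ = [
    "PeakFit",
    "PeakCriteria",
    "PeakAssessment",
    "QuantResult",
    "eic",
    "ecc",
    "fit_skewed_gaussian",
    "assess_peak",
    "fraction_modified",
    "fraction_from_areas",
]


@dataclass(frozen=True)
class PeakFit:
    """A fitted skew-normal chromatographic peak.

    ``area`` is the mass of the skew-normal component (intensity·min),
    excluding baseline; ``rt`` is the location parameter in minutes;
    ``width`` the scale parameter in minutes; ``skew`` the shape
    parameter (0 = symmetric Gaussian).
    """

    area: float
    rt: float
    width: float
    skew: float
    baseline: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and not (self.area >= 0 and self.width > 0):
            raise ValueError("converged fit requires area >= 0 and width > 0")


@dataclass(frozen=True)
class PeakCriteria:
    """Tunable thresholds for accepting an ECC peak as a real species.

    Defaults implement: more than eight charge states present within
    ±0.2 min of the peak with at least four consecutive, no other ECC
    peak above 80% of the tallest, at most two others above 40%, skew in
    [0, 1.5], and width at most 0.25 min.
    """

    min_charge_states: int = 9
    min_consecutive: int = 4
    rt_window: float = 0.2
    large_height_frac: float = 0.8
    max_other_large: int = 0
    small_height_frac: float = 0.4
    max_other_small: int = 2
    skew_range: tuple[float, float] = (0.0, 1.5)
    max_width: float = 0.25
    presence_floor: float = 0.0
    prominence_frac: float = 0.05


@dataclass(frozen=True)
class PeakAssessment:
    valid: bool
    n_charge_states: int
    n_consecutive: int
    n_large_peaks: int
    n_small_peaks: int
    reasons: tuple[str, ...]


@dataclass
class QuantResult:
    """Per-state fits and the fraction modified for one extract."""

    per_state: list[tuple[ModificationState, PeakFit | None,
                          PeakAssessment | None]]
    total_peptide_area: float
    fraction_modified: float | None
    modified_labels: frozenset[str]
    detected: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for state, fit, assessment in self.per_state:
            rows.append({
                "state": state.name,
                "label": state.label,
                "expected_mass": state.expected_mass,
                "area": fit.area if fit and assessment and assessment.valid else 0.0,
                "rt": fit.rt if fit else np.nan,
                "width": fit.width if fit else np.nan,
                "skew": fit.skew if fit else np.nan,
                "valid": bool(assessment.valid) if assessment else False,
                "reasons": ";".join(assessment.reasons) if assessment else "no_fit",
                "fraction_modified": self.fraction_modified,
            })
        return pd.DataFrame(rows)


def eic(table: SignalTable, center_mz: float, halfwidth: float) -> Chromatogram:
    """Extracted ion chromatogram: per-scan intensity within ±halfwidth.

    The time axis is the full scan grid of the table; scans without a
    matching peak contribute zero.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    grid = table.scan_times
    f = table.frame
    inside = f[(f["mz"] - center_mz).abs() <= halfwidth]
    sums = inside.groupby("rt")["intensity"].sum()
    intensity = np.zeros(len(grid))
    if len(sums):
        idx = np.searchsorted(grid, sums.index.to_numpy())
        intensity[idx] = sums.to_numpy()
    return Chromatogram(grid, intensity, kind="EIC",
                        meta={"center_mz": center_mz, "halfwidth": halfwidth})


def ecc(
    table: SignalTable,
    state: ModificationState,
    instrument: InstrumentProfile,
) -> tuple[Chromatogram, dict[int, Chromatogram]]:
    """Extracted compound chromatogram: pointwise sum of charge-state EICs.

    One EIC is extracted per charge state of the state's expected mass
    inside the instrument scan range, with window ±numerator/z Da.
    """
    charges = charges_in_range(state.expected_mass, *instrument.scan_mz_range)
    grid = table.scan_times
    per_charge: dict[int, Chromatogram] = {}
    total = np.zeros(len(grid))
    for z in charges:
        trace = eic(table, mz_for_charge(state.expected_mass, z),
                    instrument.eic_halfwidth(z))
        per_charge[z] = trace
        total += trace.intensity
    chrom = Chromatogram(grid, total, kind="ECC",
                         meta={"target_mass": state.expected_mass,
                               "charges": charges})
    return chrom, per_charge


def _skew_model(t, area, loc, scale, shape, baseline):
    return baseline + area * skewnorm.pdf(t, shape, loc=loc, scale=scale)


def fit_skewed_gaussian(chrom: Chromatogram) -> PeakFit:
    """Fit baseline + area x skew-normal density to a chromatogram.

    Deterministic initialization: location at the maximum point, scale
    from the half-height width, zero skew, baseline at the minimum.
    An all-zero trace returns a non-converged zero-area fit.
    """
    t = chrom.rt
    y = chrom.intensity
    if len(t) < 8:
        raise ValueError("need at least 8 points to fit a peak")
    ymax = float(y.max())
    if ymax <= 0:
        return PeakFit(0.0, float(t[len(t) // 2]), 0.0, 0.0, 0.0, False)

    baseline0 = float(y.min())
    i_max = int(np.argmax(y))
    loc0 = float(t[i_max])
    half = baseline0 + (ymax - baseline0) / 2.0
    above = np.nonzero(y >= half)[0]
    span = float(t[above[-1]] - t[above[0]]) if len(above) > 1 else 0.0
    scale0 = max(span / 2.3548, 2.0 * float(np.median(np.diff(t))))
    area0 = max(float(np.trapezoid(np.clip(y - baseline0, 0, None), t)), 1e-9)
    t_span = float(t[-1] - t[0])

    p0 = [area0, loc0, scale0, 0.0, baseline0]
    lower = [0.0, float(t[0]), 1e-4, -20.0, 0.0]
    upper = [np.inf, float(t[-1]), t_span, 20.0, ymax]
    p0 = [min(max(p, lo), hi if np.isfinite(hi) else p)
          for p, lo, hi in zip(p0, lower, upper)]

    result = optimize.least_squares(
        lambda p: _skew_model(t, *p) - y, p0, bounds=(lower, upper),
        xtol=1e-10, ftol=1e-10)
    area, loc, scale, shape, baseline = result.x
    converged = bool(result.success) and area > 0 and scale > 0
    return PeakFit(float(area), float(loc), float(scale), float(shape),
                   float(baseline), converged)


def _smooth3(y: np.ndarray) -> np.ndarray:
    if len(y) < 3:
        return y.copy()
    kernel = np.ones(3) / 3.0
    out = np.convolve(y, kernel, mode="same")
    # edges: average over existing neighbors only
    out[0] = y[:2].mean()
    out[-1] = y[-2:].mean()
    return out


def _secondary_peaks(
    ecc_chrom: Chromatogram, candidate_rt: float, criteria: PeakCriteria
) -> tuple[int, int]:
    """Count non-candidate ECC local maxima above the large/small cuts.

    Maxima are found on a 3-point moving mean with a prominence floor;
    the local maximum nearest the candidate retention time is the
    candidate itself and is excluded.
    """
    y = _smooth3(ecc_chrom.intensity)
    if y.max() <= 0:
        return 0, 0
    peaks, _ = signal.find_peaks(y, prominence=criteria.prominence_frac * y.max())
    if len(peaks) == 0:
        return 0, 0
    rt = ecc_chrom.rt
    nearest = peaks[np.argmin(np.abs(rt[peaks] - candidate_rt))]
    others = peaks[peaks != nearest]
    ref = float(y.max())
    heights = y[others]
    n_large = int(np.sum(heights > criteria.large_height_frac * ref))
    n_small = int(np.sum(heights > criteria.small_height_frac * ref))
    return n_large, n_small


def _longest_consecutive_run(charges: Iterable[int]) -> int:
    zs = sorted(set(charges))
    if not zs:
        return 0
    best = run = 1
    for a, b in zip(zs, zs[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best


def assess_peak(
    fit: PeakFit,
    ecc_chrom: Chromatogram,
    per_charge_eics: Mapping[int, Chromatogram],
    criteria: PeakCriteria | None = None,
) -> PeakAssessment:
    """Decide whether a fitted ECC peak is a trustworthy species.

    A charge state counts as present when its EIC exceeds the presence
    floor anywhere within ±rt_window of the fitted retention time.
    """
    criteria = criteria or PeakCriteria()
    if not fit.converged:
        return PeakAssessment(False, 0, 0, 0, 0, ("not_converged",))

    present = []
    for z, trace in per_charge_eics.items():
        window = np.abs(trace.rt - fit.rt) <= criteria.rt_window
        if np.any(trace.intensity[window] > criteria.presence_floor):
            present.append(z)
    n_present = len(present)
    n_consecutive = _longest_consecutive_run(present)
    n_large, n_small = _secondary_peaks(ecc_chrom, fit.rt, criteria)

    reasons = []
    if n_present < criteria.min_charge_states:
        reasons.append("charge_states")
    if n_consecutive < criteria.min_consecutive:
        reasons.append("consecutive")
    if n_large > criteria.max_other_large:
        reasons.append("large_peaks")
    if n_small > criteria.max_other_small:
        reasons.append("small_peaks")
    if not criteria.skew_range[0] <= fit.skew <= criteria.skew_range[1]:
        reasons.append("skew")
    if fit.width > criteria.max_width:
        reasons.append("width")
    return PeakAssessment(
        valid=not reasons,
        n_charge_states=n_present,
        n_consecutive=n_consecutive,
        n_large_peaks=n_large,
        n_small_peaks=n_small,
        reasons=tuple(reasons),
    )


def fraction_from_areas(
    areas_by_state: Sequence[tuple[str, float]],
    modified_labels: Iterable[str] = ("modified",),
) -> float | None:
    """Fraction modified from (label, valid area) pairs.

    Modified area over total peptide area; None when the total is zero.
    ``modified_labels`` widens the numerator (e.g. counting partially
    phosphorylated states as product).
    """
    labels = frozenset(modified_labels)
    total = sum(a for _, a in areas_by_state)
    if total <= 0:
        return None
    return sum(a for lab, a in areas_by_state if lab in labels) / total


def fraction_modified(
    table: SignalTable,
    peptide: str,
    deltas: Sequence[ModificationDelta],
    instrument: InstrumentProfile,
    modified_labels: Iterable[str] = ("modified",),
    criteria: PeakCriteria | None = None,
    partial_threshold: float = 15.0,
) -> QuantResult:
    """Run the full per-extract pipeline and compute fraction modified.

    States are enumerated, each is extracted as an ECC, fit, and
    assessed; invalid or absent states contribute zero area. The result
    is flagged undetected when no state yields a valid peak.
    """
    states = enumerate_states(peptide, deltas, partial_threshold)
    per_state = []
    areas: list[tuple[str, float]] = []
    for state in states:
        chrom, per_charge = ecc(table, state, instrument)
        if chrom.intensity.max() <= 0:
            per_state.append((state, None, None))
            continue
        fit = fit_skewed_gaussian(chrom)
        assessment = assess_peak(fit, chrom, per_charge, criteria)
        per_state.append((state, fit, assessment))
        if assessment.valid:
            areas.append((state.label, fit.area))

    fraction = fraction_from_areas(areas, modified_labels)
    total = sum(a for _, a in areas)
    return QuantResult(
        per_state=per_state,
        total_peptide_area=total,
        fraction_modified=fraction,
        modified_labels=frozenset(modified_labels),
        detected=bool(areas),
    )
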