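"""Centroided MS1 signal ingest, filtering, and chromatogram assembly.

The working representation is a long-form table of (retention time,
m/z, intensity) records — one row per centroid peak — held in a pandas
DataFrame. Retention times are normalized to minutes at ingest
regardless of the units the file declares.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentProfile",
    "QQQ",
    "QTOF",
    "INSTRUMENTS",
    "SignalTable",
    "Chromatogram",
    "read_mzxml",
    "filter_signals",
    "total_ion_chromatogram",
    "read_signal_tsv",
    "write_signal_tsv",
]

COLUMNS = ["rt", "mz", "intensity"]


@dataclass(frozen=True)
class InstrumentProfile:
    """Mass-spectrometer constants used across the pipeline.

    ``fwhm``/``sigma`` describe single-charge peak width in m/z; the
    mass uncertainty floor of a deconvolved species is sigma scaled by
    its largest observed charge. ``eic_halfwidth_numerator`` sets the
    extraction window ±numerator/z Da around each charge state.
    ``scan_interval`` is in seconds.
    """

    name: str
    fwhm: float
    sigma: float
    eic_halfwidth_numerator: float
    scan_mz_range: tuple[float, float]
    scan_interval: float

    def eic_halfwidth(self, z: int) -> float:
        return self.eic_halfwidth_numerator / z


# Unit-resolution triple quadrupole and high-resolution Q-TOF profiles.
# sigma is the stored instrument constant (approximately FWHM/2.3548).
QQQ = InstrumentProfile("QQQ", fwhm=0.7, sigma=0.3,
                        eic_halfwidth_numerator=2.0,
                        scan_mz_range=(500.0, 2000.0), scan_interval=0.3)
QTOF = InstrumentProfile("QTOF", fwhm=0.06, sigma=0.026,
                         eic_halfwidth_numerator=1.0,
                         scan_mz_range=(100.0, 3200.0), scan_interval=0.25)
INSTRUMENTS = {"QQQ": QQQ, "QTOF": QTOF}


@dataclass
class SignalTable:
    """Long-form centroided MS1 data: one row per (rt, mz, intensity)."""

    frame: pd.DataFrame
    source: str = ""
    instrument: InstrumentProfile | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"signal table missing columns {missing}")
        self.frame = (
            self.frame[COLUMNS]
            .astype(float)
            .sort_values(["rt", "mz"], kind="stable")
            .reset_index(drop=True)
        )
        if (self.frame["intensity"] < 0).any():
            raise ValueError("negative intensities in signal table")
        if (self.frame["rt"] < 0).any():
            raise ValueError("negative retention times in signal table")

    @classmethod
    def from_records(
        cls,
        records,
        source: str = "",
        instrument: InstrumentProfile | None = None,
    ) -> "SignalTable":
        frame = pd.DataFrame(records, columns=COLUMNS)
        return cls(frame, source=source, instrument=instrument)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def scan_times(self) -> np.ndarray:
        """Distinct retention times, ascending (the scan grid)."""
        return np.unique(self.frame["rt"].to_numpy())


@dataclass
class Chromatogram:
    """A time-intensity trace (TIC, EIC, or ECC)."""

    rt: np.ndarray
    intensity: np.ndarray
    kind: str = "EIC"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("retention times must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("negative intensities in chromatogram")


def _rt_to_minutes(rt) -> float:
    """Normalize a pyteomics retentionTime to minutes."""
    unit = getattr(rt, "unit_info", None)
    value = float(rt)
    if unit in ("second", "seconds", "s"):
        return value / 60.0
    if unit in ("hour", "hours", "h"):
        return value * 60.0
    return value  # pyteomics reports mzXML retention times in minutes


def read_mzxml(
    path: str | os.PathLike,
    min_intensity: float = 1000.0,
    ms_level: int = 1,
) -> SignalTable:
    """Read centroided scans from an mzXML file into a SignalTable.

    Peaks below ``min_intensity`` are dropped (the vendor-export
    intensity floor, applied per peak). Scans at other MS levels are
    dropped silently; their count is logged. Profile-mode scans are
    accepted with a warning — downstream windows assume centroids.
    """
    from pyteomics import mzxml

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    rts, mzs, intens = [], [], []
    n_other_level = 0
    n_profile = 0
    with mzxml.read(path) as reader:
        for scan in reader:
            if int(scan.get("msLevel", 1)) != ms_level:
                n_other_level += 1
                continue
            if not int(scan.get("centroided", 1)):
                n_profile += 1
            rt = _rt_to_minutes(scan["retentionTime"])
            mz = np.asarray(scan["m/z array"], dtype=float)
            inten = np.asarray(scan["intensity array"], dtype=float)
            keep = inten >= min_intensity
            rts.append(np.full(keep.sum(), rt))
            mzs.append(mz[keep])
            intens.append(inten[keep])

    if n_other_level:
        logger.info("dropped %d scans at msLevel != %d", n_other_level, ms_level)
    if n_profile:
        warnings.warn(
            f"{n_profile} scan(s) not flagged centroided; treating peaks "
            "as centroids", stacklevel=2)

    frame = pd.DataFrame({
        "rt": np.concatenate(rts) if rts else np.array([]),
        "mz": np.concatenate(mzs) if mzs else np.array([]),
        "intensity": np.concatenate(intens) if intens else np.array([]),
    })
    return SignalTable(frame, source=os.path.basename(path))


def filter_signals(
    table: SignalTable,
    rt_range: tuple[float, float] = (1.0, 6.0),
    mz_range: tuple[float, float] = (500.0, 2500.0),
) -> SignalTable:
    """Restrict to the analysis window (closed intervals on both axes)."""
    if rt_range[0] > rt_range[1] or mz_range[0] > mz_range[1]:
        raise ValueError("ranges must be ordered (low, high)")
    f = table.frame
    mask = (
        f["rt"].between(*rt_range) & f["mz"].between(*mz_range)
    )
    return SignalTable(f[mask].reset_index(drop=True),
                       source=table.source, instrument=table.instrument)


def total_ion_chromatogram(table: SignalTable) -> Chromatogram:
    """Per-scan sum of all intensities."""
    grouped = table.frame.groupby("rt", sort=True)["intensity"].sum()
    return Chromatogram(grouped.index.to_numpy(), grouped.to_numpy(),
                        kind="TIC", meta={"source": table.source})


def write_signal_tsv(table: SignalTable, path: str | os.PathLike) -> None:
    """Write a SignalTable as TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# source={table.source}\n")
        name = table.instrument.name if table.instrument else ""
        fh.write(f"# instrument={name}\n")
        out = table.frame.rename(columns={"rt": "rt_min"})
        out.to_csv(fh, sep="\t", index=False)


def read_signal_tsv(path: str | os.PathLike) -> SignalTable:
    """Read the TSV signal format written by :func:`write_signal_tsv`."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame = frame.rename(columns={"rt_min": "rt"})
    instrument = INSTRUMENTS.get(meta.get("instrument", ""))
    return SignalTable(frame, source=meta.get("source", os.fspath(path)),
                       instrument=instrument)
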