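"""Amino-acid mass bookkeeping, modification states, and m/z arithmetic.

Two mass scales are used throughout and are always explicit: *average*
molar masses for intact-peptide quantification (unit-resolution
instruments see the envelope centroid, not isotopes) and *monoisotopic*
masses for fragment-ion work. Mixing the scales silently is the classic
error in intact-mass work, so every mass-producing function takes a
``scale`` argument.

Masses are residue masses (water subtracted); a free peptide adds one
water. m/z construction uses the proton mass 1.00728 Da.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "MassScale",
    "PROTON_MASS",
    "WATER_AVERAGE",
    "WATER_MONOISOTOPIC",
    "RESIDUE_MASSES_AVERAGE",
    "RESIDUE_MASSES_MONOISOTOPIC",
    "DEFAULT_MODIFICATIONS",
    "HALA2_CORE",
    "ModificationDelta",
    "ModificationState",
    "residue_mass",
    "peptide_mass",
    "state_mass",
    "enumerate_states",
    "mz_for_charge",
    "charges_in_range",
    "validate_sequence",
    "load_peptide",
    "load_modifications",
]

MassScale = Literal["average", "monoisotopic"]

PROTON_MASS = 1.00728
WATER_MONOISOTOPIC = 18.01056
WATER_AVERAGE = 18.01528

# Standard 20-residue masses (water-subtracted), 5-decimal reference values.
RESIDUE_MASSES_MONOISOTOPIC: Mapping[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

RESIDUE_MASSES_AVERAGE: Mapping[str, float] = {
    "G": 57.05190, "A": 71.07880, "S": 87.07820, "P": 97.11670,
    "V": 99.13260, "T": 101.10510, "C": 103.13880, "L": 113.15940,
    "I": 113.15940, "N": 114.10380, "D": 115.08860, "Q": 128.13070,
    "K": 128.17410, "E": 129.11550, "M": 131.19260, "H": 137.14110,
    "F": 147.17660, "R": 156.18750, "Y": 163.17600, "W": 186.21320,
}

CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES_AVERAGE)

# Haloduracin beta (HalA2) core peptide, literature reference sequence.
# Contains 8 Ser/Thr residues, of which class II lanthipeptide synthetase
# HalM2 dehydrates seven.
HALA2_CORE = "TTWPCATVGVSVALCPTTKCTSQC"


def validate_sequence(sequence: str) -> str:
    """Check that ``sequence`` is a non-empty canonical peptide string."""
    if not sequence:
        raise ValueError("peptide sequence is empty")
    for ch in sequence:
        if ch not in CANONICAL_RESIDUES:
            raise ValueError(f"non-canonical residue code {ch!r} in sequence")
    return sequence


def load_peptide(source: str | os.PathLike) -> str:
    """Return a peptide sequence from a plain string or single-record FASTA.

    A path to an existing file is parsed as FASTA (exactly one record);
    anything else is treated as a literal sequence.
    """
    if os.path.exists(os.fspath(source)):
        from Bio import SeqIO

        records = list(SeqIO.parse(os.fspath(source), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected exactly one FASTA record, found {len(records)}"
            )
        return validate_sequence(str(records[0].seq).upper())
    return validate_sequence(str(source))


@dataclass(frozen=True)
class ModificationDelta:
    """A chemical modification as a signed mass shift.

    Parameters
    ----------
    name : str
        Human-readable label (e.g. ``dehydration``).
    delta_average, delta_monoisotopic : float
        Signed mass shift in Da on each scale.
    count : int
        Maximum number of times the modification can occur on one peptide.
    residue_targets : frozenset of str, optional
        Residues the modification can land on; when given, ``count`` may
        not exceed the number of target residues in the peptide.
    """

    name: str
    delta_average: float
    delta_monoisotopic: float
    count: int = 1
    residue_targets: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"{self.name}: count must be >= 1")
        if not (math.isfinite(self.delta_average)
                and math.isfinite(self.delta_monoisotopic)):
            raise ValueError(f"{self.name}: mass deltas must be finite")
        if self.residue_targets is not None:
            object.__setattr__(
                self, "residue_targets", frozenset(self.residue_targets)
            )

    def delta(self, scale: MassScale) -> float:
        return (self.delta_average if scale == "average"
                else self.delta_monoisotopic)


# Reference registry entries for the chemistries this pipeline was built
# around. These are documented literature mass shifts; real analyses
# normally supply their own registry (see load_modifications).
DEFAULT_MODIFICATIONS: Mapping[str, ModificationDelta] = {
    "dehydration": ModificationDelta(
        "dehydration", -18.01528, -18.010565,
        residue_targets=frozenset("STC")),
    "phosphorylation": ModificationDelta(
        "phosphorylation", 79.9799, 79.96633,
        residue_targets=frozenset("STY")),
    "thioether": ModificationDelta(
        "thioether", -2.01588, -2.015650),
    "hexosylation": ModificationDelta(
        "hexosylation", 162.14240, 162.052824),
    "methylation": ModificationDelta(
        "methylation", 14.02660, 14.015650),
    "acetylation": ModificationDelta(
        "acetylation", 42.03670, 42.010565),
}


@dataclass(frozen=True)
class ModificationState:
    """A peptide together with an applied multiset of modifications.

    ``applied`` pairs each delta with its occurrence count (0 < n <=
    delta.count entries are stored; zero-occurrence deltas are omitted).
    ``label`` is ``unmodified`` when nothing is applied, ``modified`` when
    every registered delta is applied at full count, and ``partial``
    otherwise.
    """

    peptide: str
    applied: tuple[tuple[ModificationDelta, int], ...]
    label: str
    expected_mass: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        validate_sequence(self.peptide)
        for delta, n in self.applied:
            if not 1 <= n <= delta.count:
                raise ValueError(
                    f"{delta.name}: applied count {n} outside 1..{delta.count}"
                )
        if math.isnan(self.expected_mass):
            object.__setattr__(
                self, "expected_mass", state_mass(self, "average")
            )

    @property
    def name(self) -> str:
        if not self.applied:
            return "unmodified"
        return "+".join(
            f"{n}x{delta.name}" for delta, n in self.applied
        )


def residue_mass(code: str, scale: MassScale) -> float:
    """Water-subtracted residue mass of a one-letter code on ``scale``."""
    table = (RESIDUE_MASSES_AVERAGE if scale == "average"
             else RESIDUE_MASSES_MONOISOTOPIC)
    try:
        return table[code]
    except KeyError:
        raise ValueError(f"unknown residue code {code!r}") from None


def peptide_mass(sequence: str, scale: MassScale) -> float:
    """Neutral mass of a free peptide: residue masses plus one water."""
    validate_sequence(sequence)
    water = WATER_AVERAGE if scale == "average" else WATER_MONOISOTOPIC
    return sum(residue_mass(ch, scale) for ch in sequence) + water


def state_mass(state: ModificationState, scale: MassScale) -> float:
    """Neutral mass of a modification state on the requested scale."""
    mass = peptide_mass(state.peptide, scale)
    for delta, n in state.applied:
        mass += n * delta.delta(scale)
    return mass


def _check_applicable(peptide: str, delta: ModificationDelta) -> None:
    if delta.residue_targets is not None:
        n_targets = sum(peptide.count(r) for r in delta.residue_targets)
        if delta.count > n_targets:
            raise ValueError(
                f"{delta.name}: count {delta.count} exceeds the "
                f"{n_targets} target residue(s) in the peptide"
            )


def enumerate_states(
    peptide: str,
    deltas: Sequence[ModificationDelta],
    partial_threshold: float = 15.0,
) -> list[ModificationState]:
    """Enumerate the modification states to search for in an extract.

    The unmodified and fully modified states are always produced.
    Intermediate occupancies are enumerated only for modifications whose
    individual mass shift is at least ``partial_threshold`` Da in
    magnitude — smaller shifts are not resolved at unit resolution, so
    their partial states would extract the same signal as their
    neighbours. Sub-threshold deltas therefore toggle all-or-none.

    Returns unique states sorted by expected (average) mass.
    """
    validate_sequence(peptide)
    for delta in deltas:
        _check_applicable(peptide, delta)

    occupancy_sets = []
    for delta in deltas:
        if abs(delta.delta_average) >= partial_threshold:
            occupancy_sets.append(range(delta.count + 1))
        else:
            occupancy_sets.append((0, delta.count))

    states: dict[tuple[int, ...], ModificationState] = {}
    for occupancy in itertools.product(*occupancy_sets):
        if occupancy in states:
            continue
        applied = tuple(
            (delta, n) for delta, n in zip(deltas, occupancy) if n > 0
        )
        if not applied:
            label = "unmodified"
        elif all(n == delta.count for delta, n in zip(deltas, occupancy)):
            label = "modified"
        else:
            label = "partial"
        states[occupancy] = ModificationState(peptide, applied, label)
    return sorted(states.values(), key=lambda s: s.expected_mass)


def mz_for_charge(mass: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """m/z of the [M+zH]z+ ion of a neutral mass."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * proton_mass) / z


def charges_in_range(mass: float, mz_min: float, mz_max: float) -> list[int]:
    """All charges whose [M+zH]z+ ion falls inside [mz_min, mz_max].

    Ascending. The closed window mirrors the instrument scan range.
    """
    if not mz_min < mz_max:
        raise ValueError("mz_min must be < mz_max")
    # z such that mz <= mz_max  <=>  z >= (mass - p... solve directly
    charges = []
    z = 1
    while True:
        mz = mz_for_charge(mass, z)
        if mz < mz_min:
            break
        if mz <= mz_max:
            charges.append(z)
        z += 1
    return charges


def load_modifications(path: str | os.PathLike) -> list[ModificationDelta]:
    """Read a modification registry from YAML or TSV.

    YAML: a list of mappings (or a name-keyed mapping) with keys
    ``name, delta_average, delta_monoisotopic, count, targets``.
    TSV: the same columns, ``targets`` as a run of residue letters or
    empty.
    """
    path = os.fspath(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if isinstance(raw, Mapping):
            raw = [{"name": k, **v} for k, v in raw.items()]
        entries = raw
    else:
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", comment="#")
        entries = frame.to_dict("records")

    deltas = []
    for e in entries:
        targets = e.get("targets") or e.get("residue_targets")
        if isinstance(targets, float):  # pandas NaN for empty cells
            targets = None
        deltas.append(ModificationDelta(
            name=str(e["name"]),
            delta_average=float(e["delta_average"]),
            delta_monoisotopic=float(e["delta_monoisotopic"]),
            count=int(e.get("count", 1) or 1),
            residue_targets=frozenset(targets) if targets else None,
        ))
    return deltas
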