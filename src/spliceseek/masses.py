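"""Peptide mass and m/z arithmetic.

Monoisotopic (default) and average residue masses are loaded from a
versioned table shipped with the package.  All masses are in daltons.
Charged species are singly/multiply protonated positive ions; the charge
carrier is the proton (1.00728 Da), with an optional "integer" convention
``(Mr + z) / z`` selectable for comparison against legacy software output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ResidueMassTable",
    "PeptideIon",
    "LabelVariant",
    "default_table",
    "peptide_mass",
    "mz_value",
    "splice_mass",
    "label_variants",
    "fragment_ions",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue masses plus the water, proton and ammonia constants."""

    mono: Mapping[str, float]
    average: Mapping[str, float]
    water: float
    water_average: float
    proton: float
    ammonia: float

    def __post_init__(self) -> None:
        missing = [r for r in CANONICAL_RESIDUES if r not in self.mono]
        if missing:
            raise ValueError(f"mass table missing residues: {missing}")

    def residue(self, letter: str, mode: str = "mono") -> float:
        try:
            return (self.mono if mode == "mono" else self.average)[letter]
        except KeyError:
            raise ValueError(f"unknown residue letter {letter!r}") from None

    def water_for(self, mode: str) -> float:
        return self.water if mode == "mono" else self.water_average


def _load_table() -> ResidueMassTable:
    mono: dict[str, float] = {}
    avg: dict[str, float] = {}
    text = resources.files("spliceseek.data").joinpath("residue_masses.tsv").read_text()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    for rec in csv.DictReader(rows, delimiter="\t"):
        mono[rec["name"]] = float(rec["monoisotopic"])
        avg[rec["name"]] = float(rec["average"])
    return ResidueMassTable(
        mono={k: v for k, v in mono.items() if len(k) == 1},
        average={k: v for k, v in avg.items() if len(k) == 1},
        water=mono["water"],
        water_average=avg["water"],
        proton=mono["proton"],
        ammonia=mono["ammonia"],
    )


_DEFAULT: ResidueMassTable | None = None


def default_table() -> ResidueMassTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_table()
    return _DEFAULT


def peptide_mass(
    sequence: str,
    table: ResidueMassTable | None = None,
    label_deltas: Mapping[int, float] | None = None,
    mode: str = "mono",
) -> float:
    """Neutral mass of a linear peptide: residue masses + one water.

    ``label_deltas`` maps 1-based sequence positions to isotope-label mass
    offsets (e.g. +6.02013 for a 13C6 lysine at that position).
    """
    if mode not in ("mono", "average"):
        raise ValueError(f"mode must be 'mono' or 'average', got {mode!r}")
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = table or default_table()
    mass = table.water_for(mode)
    for letter in sequence:
        mass += table.residue(letter, mode)
    if label_deltas:
        for pos, delta in label_deltas.items():
            if not 1 <= pos <= len(sequence):
                raise ValueError(f"label position {pos} outside sequence of length {len(sequence)}")
            mass += delta
    return mass


def mz_value(
    mr: float,
    z: int,
    table: ResidueMassTable | None = None,
    convention: str = "proton",
) -> float:
    """m/z of the z-fold protonated ion.

    ``convention='proton'`` uses (Mr + z*1.00728)/z; ``'integer'`` uses the
    nominal (Mr + z)/z (differs by up to ~0.03 at z=1 from the former).
    """
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if convention == "proton":
        proton = (table or default_table()).proton
        return (mr + z * proton) / z
    if convention == "integer":
        return (mr + z) / z
    raise ValueError(f"unknown m/z convention {convention!r}")


def neutral_mass(mz: float, z: int, table: ResidueMassTable | None = None) -> float:
    """Invert :func:`mz_value` under the proton convention."""
    proton = (table or default_table()).proton
    return mz * z - z * proton


def splice_mass(mass_first: float, mass_second: float, table: ResidueMassTable | None = None) -> float:
    """Neutral mass of the ligation of two peptides (one water condensed)."""
    return mass_first + mass_second - (table or default_table()).water


@dataclass(frozen=True)
class PeptideIon:
    sequence: str
    charge: int
    mr: float
    mz: float


@dataclass(frozen=True)
class LabelVariant:
    """One of the four light/heavy splice combinations of a fragment pair."""

    name: str                 # "light/light", "light/heavy", "heavy/light", "heavy/heavy"
    mr: float
    delta: float              # mass offset relative to light/light
    trans_only: bool          # mixed-label variants require two substrate molecules
    ion: PeptideIon = field(compare=False, default=None)  # type: ignore[assignment]


def label_variants(
    idx,
    light,
    heavy,
    table: ResidueMassTable | None = None,
    charge: int = 1,
) -> list[LabelVariant]:
    """The four light/heavy variants of a spliced fragment pair.

    ``idx`` is a :class:`~spliceseek.enumeration.SpliceIndex` on the shared
    letter sequence; ``heavy`` carries per-position label offsets.  Deltas
    relative to light/light are {0, d2, d1, d1+d2} where d1/d2 sum the heavy
    offsets falling inside the first/second fragment.  The two mixed-label
    variants can only arise from two substrate molecules and are flagged
    ``trans_only``.
    """
    if light.sequence != heavy.sequence:
        raise ValueError("light and heavy substrates must share the same letter sequence")
    table = table or default_table()
    offsets = heavy.label_offsets or {}
    d1 = sum(v for p, v in offsets.items() if idx.first.i <= p <= idx.first.j)
    d2 = sum(v for p, v in offsets.items() if idx.second.i <= p <= idx.second.j)
    seq = (
        light.sequence[idx.first.i - 1 : idx.first.j]
        + light.sequence[idx.second.i - 1 : idx.second.j]
    )
    base = peptide_mass(seq, table)
    out = []
    for name, delta, mixed in (
        ("light/light", 0.0, False),
        ("light/heavy", d2, True),
        ("heavy/light", d1, True),
        ("heavy/heavy", d1 + d2, False),
    ):
        mr = base + delta
        ion = PeptideIon(seq, charge, mr, mz_value(mr, charge, table))
        out.append(LabelVariant(name, mr, delta, mixed, ion))
    return out


def fragment_ions(
    sequence: str,
    series: Iterable[str] = ("b", "y"),
    losses: Sequence[str] = (),
    z: int = 1,
    table: ResidueMassTable | None = None,
) -> list[tuple[str, float]]:
    """Singly-indexed b/y fragment-ion m/z values.

    ``losses`` may contain ``"°"`` (water loss) and/or ``"*"`` (ammonia
    loss); each requested loss adds a parallel annotated series.
    """
    if len(sequence) < 2:
        raise ValueError("fragment ions need a sequence of length >= 2")
    table = table or default_table()
    bad = set(series) - {"b", "y"}
    if bad:
        raise ValueError(f"unsupported ion series: {sorted(bad)}")
    loss_mass = {"": 0.0, "°": table.water, "*": table.ammonia}
    for s in losses:
        if s not in ("°", "*"):
            raise ValueError(f"unsupported loss symbol {s!r}")
    ions: list[tuple[str, float]] = []
    residue_masses = [table.residue(a) for a in sequence]
    suffix_totals: list[float] = []
    acc = 0.0
    for m in reversed(residue_masses):
        acc += m
        suffix_totals.append(acc)
    if "b" in series:
        prefix = 0.0
        for i in range(1, len(sequence)):
            prefix += residue_masses[i - 1]
            for s in ("",) + tuple(losses):
                ions.append((f"b{i}{s}", (prefix + z * table.proton - loss_mass[s]) / z))
    if "y" in series:
        for i in range(1, len(sequence) + 1):
            base = suffix_totals[i - 1] + table.water
            for s in ("",) + tuple(losses):
                ions.append((f"y{i}{s}", (base + z * table.proton - loss_mass[s]) / z))
    return ions
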