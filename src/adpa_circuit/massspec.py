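"""In-silico support for persulfide proteomics: tryptic digestion,
monoisotopic masses of carbamidomethylated (AM) and
persulfide-carbamidomethylated (S-AM) peptides, and observed-mass matching.

Chemistry background: free cysteine thiols are blocked with iodoacetamide,
adding +57.02146 Da (carbamidomethyl).  A persulfidated cysteine
(Cys-SSH) carries one extra sulfur before blocking, so its blocked form is
heavier by exactly one sulfur atom, +31.97207 Da — the "+32" signature
that distinguishes the two peptide states in MS1.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ProteinRecord",
    "Peptide",
    "ModSpec",
    "PeptideMatch",
    "CARBAMIDOMETHYL",
    "PERSULFIDE_CARBAMIDOMETHYL",
    "WATER_MONO",
    "PROTON_MASS",
    "SULFUR_MONO",
    "tryptic_digest",
    "monoisotopic_mass",
    "match_masses",
    "intensity_ratio",
    "mz_from_neutral",
    "neutral_from_mz",
    "read_fasta",
]

# Monoisotopic residue masses (Da), standard amino-acid residue values
# (Unimod/IUPAC 2021 atomic masses), stored to 5 decimals.
RESIDUE_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MASS = 1.007276
SULFUR_MONO = 31.97207

_CANONICAL = set(RESIDUE_MONO)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence of the 20 canonical residues."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in _CANONICAL:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {i} in {self.id}")


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 1-based inclusive coordinates in its parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass(frozen=True)
class ModSpec:
    """A residue-targeted mass modification (monoisotopic delta, Da)."""

    name: str
    target_residue: str
    delta_mass: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_mass):
            raise ValueError("delta_mass must be finite")
        if self.target_residue not in _CANONICAL:
            raise ValueError(f"unknown target residue {self.target_residue!r}")


CARBAMIDOMETHYL = ModSpec("carbamidomethyl", "C", 57.02146)
PERSULFIDE_CARBAMIDOMETHYL = ModSpec(
    "persulfide-carbamidomethyl", "C", 57.02146 + SULFUR_MONO)


@dataclass(frozen=True)
class PeptideMatch:
    peptide: Peptide
    mods: tuple
    theoretical_mass: float
    observed_mass: float
    error_ppm: float


def tryptic_digest(p: ProteinRecord, max_missed: int = 0) -> list[Peptide]:
    """Tryptic peptides of ``p`` with up to ``max_missed`` missed cleavages.

    Cleaves C-terminal to K or R except when the next residue is P
    (the conventional rule).  Coordinates are 1-based inclusive.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = p.sequence
    n = len(seq)
    # cut positions: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(1, n):
        if seq[i - 1] in "KR" and seq[i] != "P":
            cuts.append(i)
    cuts.append(n)
    peptides = []
    for a in range(len(cuts) - 1):
        for skip in range(max_missed + 1):
            b = a + 1 + skip
            if b >= len(cuts):
                break
            start, end = cuts[a], cuts[b]
            peptides.append(Peptide(sequence=seq[start:end],
                                    start=start + 1, end=end,
                                    missed_cleavages=skip))
    return peptides


def monoisotopic_mass(pep: Peptide | str, mods=()) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas.

    Every modification's target residue must occur in the peptide.
    """
    seq = pep.sequence if isinstance(pep, Peptide) else pep
    mass = WATER_MONO
    for aa in seq:
        try:
            mass += RESIDUE_MONO[aa]
        except KeyError:
            raise ValueError(f"non-canonical residue {aa!r} in peptide") from None
    for mod in mods:
        if mod.target_residue not in seq:
            raise ValueError(
                f"mod {mod.name!r} targets {mod.target_residue!r}, absent from {seq}")
        mass += mod.delta_mass
    return mass


def _mod_assignments(pep: Peptide, menu) -> list[tuple]:
    """All per-residue modification assignments from the menu.

    Each occurrence of a targeted residue independently carries either no
    modification or one menu modification; assignments are deduplicated by
    the multiset of applied mods.
    """
    assignments = {(): ()}
    for aa in pep.sequence:
        applicable = [m for m in menu if m.target_residue == aa]
        if not applicable:
            continue
        new = {}
        for key, mods in assignments.items():
            new[key] = mods
            for m in applicable:
                k = tuple(sorted(key + (m.name,)))
                new.setdefault(k, mods + (m,))
        assignments = new
    return list(assignments.values())


def match_masses(protein: ProteinRecord, observed, mods_menu=(),
                 max_missed: int = 0, tol_ppm: float = 10.0) -> list[PeptideMatch]:
    """Match observed neutral masses against the modified tryptic digest.

    For each observed mass, every (peptide, modification assignment) whose
    theoretical mass lies within ``tol_ppm`` is reported, ordered by
    |ppm error| then by start coordinate.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    peptides = tryptic_digest(protein, max_missed=max_missed)
    theoretical = []
    for pep in peptides:
        for mods in _mod_assignments(pep, mods_menu):
            theoretical.append((pep, mods, monoisotopic_mass(pep, mods)))
    matches = []
    for obs in observed:
        obs = float(obs)
        for pep, mods, mass in theoretical:
            err = (obs - mass) / mass * 1e6
            if abs(err) <= tol_ppm:
                matches.append(PeptideMatch(
                    peptide=pep, mods=mods, theoretical_mass=mass,
                    observed_mass=obs, error_ppm=err))
    matches.sort(key=lambda m: (abs(m.error_ppm), m.peptide.start))
    return matches


def matches_to_frame(matches) -> pd.DataFrame:
    return pd.DataFrame([
        {"peptide": m.peptide.sequence, "start": m.peptide.start,
         "end": m.peptide.end, "missed_cleavages": m.peptide.missed_cleavages,
         "mods": ";".join(mod.name for mod in m.mods),
         "theoretical_mass_da": m.theoretical_mass,
         "observed_mass_da": m.observed_mass,
         "error_ppm": m.error_ppm}
        for m in matches])


def intensity_ratio(i_a: float, i_b: float) -> float:
    """MS1 intensity ratio a/b as a percentage, 2 decimals."""
    if i_b <= 0:
        raise ValueError("denominator intensity must be > 0")
    return round(100.0 * i_a / i_b, 2)


def mz_from_neutral(mass: float, z: int) -> float:
    """m/z of a z-protonated ion from the neutral monoisotopic mass."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (mass + z * PROTON_MASS) / z


def neutral_from_mz(mz: float, z: int) -> float:
    if z < 1:
        raise ValueError("charge must be >= 1")
    return mz * z - z * PROTON_MASS


def read_fasta(path) -> ProteinRecord:
    """First record of a FASTA file as a ProteinRecord."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return ProteinRecord(id=rec.id, sequence=str(rec.seq).upper().rstrip("*"))
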