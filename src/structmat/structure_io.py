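"""Multi-model PDB ensemble I/O and peptide/receptor/core annotation.

An :class:`EnsembleComplex` holds an ordered series of conformational frames
of one peptide bound in the groove of a two-chain receptor, together with the
annotation of which peptide residues form the 9-mer binding core.  Reading
goes through Biopython's PDB parser; writing emits fixed-width PDB records so
the round trip preserves chain ids, author residue numbering, atom names and
coordinates to the format's 3-decimal precision.

Conventions
-----------
* Sequence offsets (``core_start``) are 0-based internally; PDB residue
  numbers (author field, typically 1-based) are preserved verbatim.
* Alternate locations: the highest-occupancy conformer is kept, ties broken
  by altloc letter ('A' first).
* Waters and heteroatoms are dropped on read unless ``keep_het=True``.
* Per-frame energies come from a sidecar TSV with header ``frame<TAB>energy``
  (frame indices are 0-based positions in MODEL order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlphabetError,
    ChainNotFoundError,
    CoreBoundsError,
    FormatError,
    TopologyMismatchError,
    ValidationError,
)

#: Standard 20 amino acids, 3-letter -> 1-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

CORE_LENGTH = 9


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame (author numbering preserved)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Å

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError(
                f"atom {self.chain_id}/{self.residue_number}/{self.atom_name}: "
                "position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class Frame:
    """One snapshot of the complex; ``energy`` is the optional per-frame score
    (arbitrary units, lower = better)."""

    index: int
    atoms: tuple[AtomRecord, ...]
    energy: float | None = None

    def __post_init__(self):
        self.atoms = tuple(self.atoms)
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValidationError(f"frame {self.index}: duplicate atom keys")

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom_keys(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(a.key for a in self.atoms)

    def atoms_of_chain(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def atoms_of_chains(self, chain_ids: Iterable[str]) -> list[AtomRecord]:
        wanted = set(chain_ids)
        return [a for a in self.atoms if a.chain_id in wanted]

    def find_atom(self, chain_id: str, residue_number: int,
                  atom_name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.key == (chain_id, residue_number, atom_name):
                return a
        return None


@dataclass(frozen=True)
class CoreAssignment:
    """Location of the 9-residue binding core within the peptide sequence."""

    peptide_sequence: str
    core_start: int  # 0-based offset

    def __post_init__(self):
        seq = self.peptide_sequence
        bad = set(seq) - set(ONE_TO_THREE)
        if bad:
            raise AlphabetError(f"non-standard peptide letters: {sorted(bad)}")
        if self.core_start < 0 or self.core_start + CORE_LENGTH > len(seq):
            raise CoreBoundsError(
                f"core window [{self.core_start}, {self.core_start + CORE_LENGTH}) "
                f"out of range for peptide of length {len(seq)}"
            )

    @property
    def core_sequence(self) -> str:
        return self.peptide_sequence[self.core_start:self.core_start + CORE_LENGTH]


@dataclass
class EnsembleComplex:
    """Ordered frames of an annotated peptide-receptor complex."""

    frames: list[Frame]
    peptide_chain: str
    receptor_chains: frozenset[str]
    core: CoreAssignment

    def __post_init__(self):
        self.receptor_chains = frozenset(self.receptor_chains)
        if not self.frames:
            raise ValidationError("ensemble must contain at least one frame")
        if self.peptide_chain in self.receptor_chains:
            raise ValidationError("peptide chain must be disjoint from receptor chains")
        ref = self.frames[0].atom_keys()
        for fr in self.frames[1:]:
            if fr.atom_keys() != ref:
                raise TopologyMismatchError(
                    f"frame {fr.index} differs in atom count/order from frame "
                    f"{self.frames[0].index}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def energies(self) -> np.ndarray | None:
        vals = [fr.energy for fr in self.frames]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)

    def peptide_residue_numbers(self) -> list[int]:
        """Author residue numbers of the peptide chain, in first-appearance order."""
        seen: list[int] = []
        for a in self.frames[0].atoms:
            if a.chain_id == self.peptide_chain and a.residue_number not in seen:
                seen.append(a.residue_number)
        return seen

    def core_residue_numbers(self) -> list[int]:
        """Residue numbers of the 9 core positions (core position 1..9 order)."""
        resnums = self.peptide_residue_numbers()
        return resnums[self.core.core_start:self.core.core_start + CORE_LENGTH]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _select_altloc(atom):
    """Pick the highest-occupancy conformer; ties broken by altloc letter."""
    if not atom.is_disordered():
        return atom
    children = list(atom.disordered_get_list())
    children.sort(key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))
    return children[0]


def read_energy_table(path: str | Path) -> dict[int, float]:
    """Read a sidecar TSV with header ``frame<TAB>energy``."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["frame", "energy"]:
        raise FormatError(
            f"{path}: energy sidecar must have header 'frame<TAB>energy', "
            f"got {list(df.columns)}"
        )
    return {int(r.frame): float(r.energy) for r in df.itertuples()}


def read_ensemble(
    path: str | Path,
    peptide_chain: str,
    receptor_chains: Iterable[str],
    core_start: int,
    energies: str | Path | dict[int, float] | None = None,
    keep_het: bool = False,
) -> EnsembleComplex:
    """Read a (multi-model) PDB file into an :class:`EnsembleComplex`.

    One :class:`Frame` is produced per MODEL record, in file order.  Raises
    :class:`ChainNotFoundError` if a named chain is missing,
    :class:`TopologyMismatchError` if frames differ in atoms, and
    :class:`CoreBoundsError` if the core window does not fit the peptide.
    """
    from Bio.PDB import PDBParser

    receptor_chains = frozenset(receptor_chains)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))

    if isinstance(energies, (str, Path)):
        energies = read_energy_table(energies)

    frames: list[Frame] = []
    for fidx, model in enumerate(structure):
        records: list[AtomRecord] = []
        for chain in model:
            for residue in chain:
                hetfield = residue.id[0]
                if hetfield != " " and not keep_het:
                    continue
                for atom in residue:
                    atom = _select_altloc(atom)
                    element = (atom.element or "").strip()
                    records.append(AtomRecord(
                        chain_id=chain.id,
                        residue_number=residue.id[1],
                        residue_name=residue.get_resname().strip(),
                        atom_name=atom.get_name().strip(),
                        element=element,
                        position=np.asarray(atom.get_coord(), dtype=float),
                    ))
        energy = None
        if energies is not None:
            energy = energies.get(fidx)
        frames.append(Frame(index=fidx, atoms=tuple(records), energy=energy))

    if not frames:
        raise FormatError(f"{path}: no MODEL/atom records found")

    ref_keys = frames[0].atom_keys()
    for fr in frames[1:]:
        if fr.atom_keys() != ref_keys:
            raise TopologyMismatchError(
                f"{path}: MODEL {fr.index + 1} differs in atom count/order "
                "from the first model")

    chain_ids = {a.chain_id for a in frames[0].atoms}
    for cid in sorted(receptor_chains | {peptide_chain}):
        if cid not in chain_ids:
            raise ChainNotFoundError(f"{path}: chain '{cid}' not found "
                                     f"(present: {sorted(chain_ids)})")

    # Peptide sequence in first-appearance residue order.
    seq_letters = []
    seen: set[int] = set()
    for a in frames[0].atoms:
        if a.chain_id == peptide_chain and a.residue_number not in seen:
            seen.add(a.residue_number)
            try:
                seq_letters.append(THREE_TO_ONE[a.residue_name])
            except KeyError:
                raise AlphabetError(
                    f"{path}: non-standard peptide residue "
                    f"'{a.residue_name}' at {a.residue_number}"
                )
    core = CoreAssignment(peptide_sequence="".join(seq_letters),
                          core_start=core_start)

    return EnsembleComplex(frames=frames, peptide_chain=peptide_chain,
                           receptor_chains=receptor_chains, core=core)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    """PDB columns 13-16: single-letter elements start in column 14."""
    if len(name) > 4:
        raise FormatError(f"atom name '{name}' exceeds 4 characters")
    if len(name) < 4 and len(element) == 1:
        return (" " + name).ljust(4)
    return name.ljust(4)


def write_ensemble(ensemble: EnsembleComplex, path: str | Path) -> None:
    """Write a multi-model PDB readable by :func:`read_ensemble`.

    The round trip preserves chain ids, residue numbering, atom names and
    coordinates to 3 decimals (PDB fixed width).
    """
    multi = ensemble.n_frames > 1
    lines: list[str] = []
    for fidx, frame in enumerate(ensemble.frames):
        if multi:
            lines.append(f"MODEL     {fidx + 1:4d}")
        serial = 0
        prev_chain = None
        for a in frame.atoms:
            if prev_chain is not None and a.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = a.chain_id
            serial = min(serial + 1, 99999)
            name = _format_atom_name(a.atom_name, a.element)
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {name} {a.residue_name:>3s} "
                f"{a.chain_id:1s}{a.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_energy_table(energies: Sequence[float], path: str | Path) -> None:
    """Write the sidecar energy TSV (``frame<TAB>energy``)."""
    df = pd.DataFrame({"frame": np.arange(len(energies)),
                       "energy": np.asarray(energies, dtype=float)})
    df.to_csv(path, sep="\t", index=False)
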