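"""Structural observables of a peptide-receptor ensemble.

Per frame, the module counts (i) non-bonded contacts between peptide-core
atoms and receptor atoms within a distance cutoff, and (ii) hydrogen bonds in
which the peptide-side partner is a main-chain atom (amide N as donor,
carbonyl O as acceptor).  It also measures side-chain χ1/χ2 dihedrals of
peptide residues and compares dihedral distributions between two ensembles
via the Kullback-Leibler divergence over a fixed angular binning.

Contact counting uses a k-d tree for the neighbour search followed by an
exact Euclidean refilter, so the result is identical to a brute-force
all-pairs scan with the same inclusive ``distance <= cutoff`` rule.

Hydrogen-bond geometry follows HBPLUS-like criteria: donor-acceptor distance,
hydrogen-acceptor distance and donor-H-acceptor angle.  Amide hydrogens
absent from the input (the usual case for crystal-derived frames) are placed
geometrically in the peptide-bond plane; donors whose hydrogen cannot be
reconstructed (receptor side-chain hydroxyls/amines without explicit H) fall
back to the donor-acceptor distance criterion alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import MissingDataError, ParameterError, ValidationError
from .structure_io import CORE_LENGTH, AtomRecord, EnsembleComplex, Frame

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Hydrogen-bond chemistry tables
# ---------------------------------------------------------------------------

#: Side-chain donor atoms per residue type (heavy atom carrying the H).
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

#: Nitrogen acceptors (everything with element O also accepts).
NITROGEN_ACCEPTORS = {"HIS": ("ND1", "NE2")}


def _is_acceptor(atom: AtomRecord) -> bool:
    if atom.element == "O":
        return True
    return atom.atom_name in NITROGEN_ACCEPTORS.get(atom.residue_name, ())


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (distances in Å, angles in degrees).

    Defaults mirror commonly used HBPLUS-style geometry.  The two auxiliary
    angle criteria (H-A-AA and D-A-AA) are implemented but disabled by
    default (``None``).
    """

    d_a_max: float = 3.9
    h_a_max: float = 2.5
    theta_min_deg: float = 90.0
    h_a_aa_min_deg: float | None = None
    d_a_aa_min_deg: float | None = None


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_amide_hydrogen(n_pos: np.ndarray, ca_pos: np.ndarray,
                         c_prev_pos: np.ndarray) -> np.ndarray:
    """Place the backbone amide hydrogen of a chain-interior residue.

    H lies 1.00 Å from N, in the C(i-1)-N-CA plane, along the direction
    opposing the bisector of the C(i-1)-N and CA-N bonds.
    """
    n_pos = np.asarray(n_pos, dtype=float)
    u1 = c_prev_pos - n_pos
    u2 = ca_pos - n_pos
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    bis = u1 + u2
    norm = np.linalg.norm(bis)
    if norm < 1e-8:
        raise ValidationError("degenerate C(i-1)-N-CA geometry: collinear opposing bonds")
    return n_pos - bis / norm


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def count_contacts(
    frame: Frame,
    peptide_chain: str,
    receptor_chains: Iterable[str],
    core_residue_numbers: Sequence[int],
    cutoff: float = 4.0,
    include_hydrogens: bool = False,
) -> tuple[np.ndarray, int]:
    """Count peptide-receptor atom pairs within ``cutoff`` Å (inclusive).

    Returns ``(per_position, total)`` where ``per_position[k]`` is the count
    for core position ``k+1``.  Heavy atoms only unless ``include_hydrogens``.
    """
    if cutoff <= 0:
        raise ParameterError(f"contact cutoff must be positive, got {cutoff}")
    core_set = list(core_residue_numbers)
    if len(core_set) != CORE_LENGTH:
        raise ParameterError("core_residue_numbers must list 9 residues")

    def keep(a: AtomRecord) -> bool:
        return include_hydrogens or a.element != "H"

    rec_atoms = [a for a in frame.atoms_of_chains(receptor_chains) if keep(a)]
    pep_atoms = [a for a in frame.atoms_of_chain(peptide_chain)
                 if keep(a) and a.residue_number in core_set]

    per_position = np.zeros(CORE_LENGTH, dtype=int)
    if not rec_atoms or not pep_atoms:
        return per_position, 0

    rec_xyz = np.array([a.position for a in rec_atoms])
    tree = cKDTree(rec_xyz)
    pos_of_resnum = {rn: i for i, rn in enumerate(core_set)}
    for a in pep_atoms:
        # slightly inflated query radius, then exact refilter: guarantees
        # agreement with a brute-force <= comparison at the boundary
        idx = tree.query_ball_point(a.position, cutoff * (1.0 + 1e-9) + 1e-9)
        n = 0
        for j in idx:
            if np.linalg.norm(rec_xyz[j] - a.position) <= cutoff:
                n += 1
        per_position[pos_of_resnum[a.residue_number]] += n
    return per_position, int(per_position.sum())


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _residue_atoms(frame: Frame, chain: str) -> dict[int, dict[str, AtomRecord]]:
    out: dict[int, dict[str, AtomRecord]] = {}
    for a in frame.atoms_of_chain(chain):
        out.setdefault(a.residue_number, {})[a.atom_name] = a
    return out


def _chain_residue_order(frame: Frame, chain: str) -> list[int]:
    seen: list[int] = []
    for a in frame.atoms_of_chain(chain):
        if a.residue_number not in seen:
            seen.append(a.residue_number)
    return seen


def _explicit_hydrogens(frame: Frame, donor: AtomRecord,
                        max_dist: float = 1.2) -> list[np.ndarray]:
    """Hydrogen atoms of the same residue within bonding distance of donor."""
    out = []
    for a in frame.atoms:
        if (a.element == "H" and a.chain_id == donor.chain_id
                and a.residue_number == donor.residue_number):
            if np.linalg.norm(a.position - donor.position) <= max_dist:
                out.append(a.position)
    return out


def _donor_hydrogens(frame: Frame, chain: str, resnum: int,
                     donor: AtomRecord,
                     residues: dict[int, dict[str, AtomRecord]],
                     order: list[int]) -> list[np.ndarray] | None:
    """Hydrogen positions for a donor atom; ``None`` means the hydrogen is
    unknown (distance-only fallback); ``[]`` means the atom cannot donate."""
    explicit = _explicit_hydrogens(frame, donor)
    if explicit:
        return explicit
    if donor.atom_name == "N":
        if donor.residue_name == "PRO":
            return []
        i = order.index(resnum)
        if i == 0:
            return []  # chain start: no preceding carbonyl, cannot place H
        prev = residues.get(order[i - 1], {})
        ca = residues.get(resnum, {}).get("CA")
        c_prev = prev.get("C")
        if ca is None or c_prev is None:
            return None
        return [place_amide_hydrogen(donor.position, ca.position, c_prev.position)]
    return None  # side-chain donor without explicit hydrogen


def _passes(donor: AtomRecord, h_positions: list[np.ndarray] | None,
            acceptor: AtomRecord, criteria: HBondCriteria,
            acceptor_antecedent: np.ndarray | None = None) -> bool:
    d_a = float(np.linalg.norm(acceptor.position - donor.position))
    if d_a > criteria.d_a_max:
        return False
    if criteria.d_a_aa_min_deg is not None and acceptor_antecedent is not None:
        if _angle_deg(donor.position, acceptor.position,
                      acceptor_antecedent) < criteria.d_a_aa_min_deg:
            return False
    if h_positions is None:
        return True  # hydrogen unknown: distance-only criterion
    for h in h_positions:
        h_a = float(np.linalg.norm(acceptor.position - h))
        if h_a > criteria.h_a_max:
            continue
        if _angle_deg(donor.position, h, acceptor.position) < criteria.theta_min_deg:
            continue
        if criteria.h_a_aa_min_deg is not None and acceptor_antecedent is not None:
            if _angle_deg(h, acceptor.position,
                          acceptor_antecedent) < criteria.h_a_aa_min_deg:
                continue
        return True
    return False


def count_backbone_hbonds(
    frame: Frame,
    peptide_chain: str,
    receptor_chains: Iterable[str],
    core_residue_numbers: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[np.ndarray, int]:
    """Count peptide main-chain hydrogen bonds with the receptor per core residue.

    For each core residue, bonds through the backbone amide N (donor) and the
    backbone carbonyl O (acceptor) are counted against every receptor
    acceptor/donor.  Residues missing backbone atoms are skipped with a
    warning, not a failure.
    """
    core_set = list(core_residue_numbers)
    if len(core_set) != CORE_LENGTH:
        raise ParameterError("core_residue_numbers must list 9 residues")

    pep_residues = _residue_atoms(frame, peptide_chain)
    pep_order = _chain_residue_order(frame, peptide_chain)

    rec_chains = sorted(set(receptor_chains))
    rec_residues = {c: _residue_atoms(frame, c) for c in rec_chains}
    rec_order = {c: _chain_residue_order(frame, c) for c in rec_chains}

    rec_acceptors: list[AtomRecord] = []
    rec_donors: list[tuple[str, int, AtomRecord]] = []
    for c in rec_chains:
        for rn, atoms in rec_residues[c].items():
            for a in atoms.values():
                if a.element == "H":
                    continue
                if _is_acceptor(a):
                    rec_acceptors.append(a)
                if a.atom_name == "N" or a.atom_name in SIDECHAIN_DONORS.get(
                        a.residue_name, ()):
                    rec_donors.append((c, rn, a))

    per_position = np.zeros(CORE_LENGTH, dtype=int)
    for k, rn in enumerate(core_set):
        atoms = pep_residues.get(rn)
        if atoms is None or not {"N", "CA", "C", "O"} <= set(atoms):
            logger.warning("core residue %s/%d missing backbone atoms; skipped",
                           peptide_chain, rn)
            continue
        n_bonds = 0

        # peptide amide N as donor
        donor = atoms["N"]
        h_pos = _donor_hydrogens(frame, peptide_chain, rn, donor,
                                 pep_residues, pep_order)
        if h_pos:  # [] or None both disable the donor path for the peptide N
            for acc in rec_acceptors:
                if _passes(donor, h_pos, acc, criteria):
                    n_bonds += 1

        # peptide carbonyl O as acceptor
        acceptor = atoms["O"]
        for c, drn, datom in rec_donors:
            h_pos = _donor_hydrogens(frame, c, drn, datom,
                                     rec_residues[c], rec_order[c])
            if h_pos == []:
                continue
            if _passes(datom, h_pos, acceptor, criteria):
                n_bonds += 1

        per_position[k] = n_bonds
    return per_position, int(per_position.sum())


# ---------------------------------------------------------------------------
# Side-chain dihedrals
# ---------------------------------------------------------------------------

#: Fourth atom of χ1 (N-CA-CB-X) per residue; residues absent have no χ1.
CHI1_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}
#: Fourth atom of χ2 (CA-CB-X-Y) per residue; residues absent have no χ2.
CHI2_ATOM = {
    "ARG": "CD", "ASN": "OD1", "ASP": "OD1", "GLN": "CD", "GLU": "CD",
    "HIS": "ND1", "ILE": "CD1", "LEU": "CD1", "LYS": "CD", "MET": "SD",
    "PHE": "CD1", "PRO": "CD", "TRP": "CD1", "TYR": "CD1",
}

STANDARD_RESIDUES = set(CHI1_ATOM) | {"GLY", "ALA"}


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed torsion angle of four points, in [-180, 180) degrees."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return ((ang + 180.0) % 360.0) - 180.0


def chi_dihedrals(frame: Frame, chain: str,
                  residue_number: int) -> tuple[float | None, float | None]:
    """χ1 and χ2 (degrees, [-180, 180)) of one residue; ``None`` when the
    residue type lacks the angle (e.g. Gly/Ala have no χ1)."""
    atoms = _residue_atoms(frame, chain).get(residue_number)
    if atoms is None:
        raise ValidationError(f"residue {chain}/{residue_number} not in frame")
    resname = next(iter(atoms.values())).residue_name
    if resname not in STANDARD_RESIDUES:
        raise ValidationError(f"unsupported residue '{resname}'")

    chi1 = chi2 = None
    g_name = CHI1_ATOM.get(resname)
    if g_name and {"N", "CA", "CB", g_name} <= set(atoms):
        chi1 = dihedral_deg(atoms["N"].position, atoms["CA"].position,
                            atoms["CB"].position, atoms[g_name].position)
        d_name = CHI2_ATOM.get(resname)
        if d_name and d_name in atoms:
            chi2 = dihedral_deg(atoms["CA"].position, atoms["CB"].position,
                                atoms[g_name].position, atoms[d_name].position)
    return chi1, chi2


DEFAULT_BIN_EDGES = np.arange(-180.0, 180.0 + 1e-9, 10.0)  # 36 bins of 10°


@dataclass
class DihedralDistribution:
    """Samples of one side-chain dihedral over an ensemble."""

    angle_name: str  # 'chi1' or 'chi2'
    samples: np.ndarray
    bin_edges: np.ndarray = field(default_factory=lambda: DEFAULT_BIN_EDGES.copy())

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValidationError("dihedral distribution needs >= 1 sample")
        if np.any(self.samples < -180.0) or np.any(self.samples >= 180.0):
            raise ValidationError("dihedral samples must lie in [-180, 180)")

    def probabilities(self) -> np.ndarray:
        """Histogram probabilities with pseudocount 1/(n_samples * n_bins)."""
        counts, _ = np.histogram(self.samples, bins=self.bin_edges)
        n_bins = len(counts)
        pseudo = 1.0 / (self.samples.size * n_bins)
        p = counts.astype(float) + pseudo
        return p / p.sum()


def collect_dihedrals(ensemble: EnsembleComplex, residue_number: int,
                      angle: str) -> DihedralDistribution:
    """Gather χ1 or χ2 of one peptide residue across all frames."""
    if angle not in ("chi1", "chi2"):
        raise ParameterError(f"angle must be chi1 or chi2, got '{angle}'")
    samples = []
    for fr in ensemble.frames:
        chi1, chi2 = chi_dihedrals(fr, ensemble.peptide_chain, residue_number)
        val = chi1 if angle == "chi1" else chi2
        if val is not None:
            samples.append(val)
    if not samples:
        raise MissingDataError(
            f"residue {residue_number} has no {angle} in this ensemble")
    return DihedralDistribution(angle_name=angle, samples=np.array(samples))


def kl_from_probs(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(P||Q) = sum P ln(P/Q) for two probability vectors (natural log)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_divergence(p: DihedralDistribution, q: DihedralDistribution) -> float:
    """Kullback-Leibler divergence between two dihedral distributions.

    Histograms over shared bin edges, pseudocount-regularized; 0 iff the
    regularized histograms are identical.
    """
    if not np.array_equal(p.bin_edges, q.bin_edges):
        raise ParameterError("distributions must share identical bin edges")
    return kl_from_probs(p.probabilities(), q.probabilities())


# ---------------------------------------------------------------------------
# Per-frame observable tables and ensemble summaries
# ---------------------------------------------------------------------------

OBSERVABLE_COLUMNS = ["run_id", "frame", "core_position", "amino_acid",
                      "hbonds", "contacts", "energy"]


@dataclass
class ObservableTable:
    """Per-frame, per-core-position counts for one simulation run.

    ``df`` has columns frame, core_position (1..9), amino_acid, hbonds,
    contacts, energy (NaN when the run carries no per-frame score).
    """

    run_id: str
    df: pd.DataFrame
    n_frames: int

    def __post_init__(self):
        expected = {"frame", "core_position", "amino_acid", "hbonds", "contacts"}
        missing = expected - set(self.df.columns)
        if missing:
            raise ValidationError(f"observable table missing columns {sorted(missing)}")
        if "energy" not in self.df.columns:
            self.df = self.df.assign(energy=np.nan)
        counts = self.df.groupby(["frame", "core_position"]).size()
        if (counts != 1).any():
            raise ValidationError("exactly one record per (frame, core_position) required")
        if len(self.df) != self.n_frames * CORE_LENGTH:
            raise ValidationError("record count inconsistent with n_frames")

    def frame_totals(self, observable: str) -> np.ndarray:
        """Per-frame core-region totals of 'hbonds' or 'contacts'."""
        if observable not in ("hbonds", "contacts"):
            raise ParameterError(f"unknown observable '{observable}'")
        return (self.df.groupby("frame")[observable].sum()
                .sort_index().to_numpy(dtype=float))

    def frame_energies(self) -> np.ndarray | None:
        e = (self.df.groupby("frame")["energy"].first().sort_index()
             .to_numpy(dtype=float))
        return None if np.isnan(e).any() else e


def compute_observables(
    ensemble: EnsembleComplex,
    run_id: str,
    cutoff: float = 4.0,
    criteria: HBondCriteria = HBondCriteria(),
    include_hydrogens: bool = False,
) -> ObservableTable:
    """Measure contacts and backbone hydrogen bonds for every frame."""
    core_resnums = ensemble.core_residue_numbers()
    core_seq = ensemble.core.core_sequence
    rows = []
    for fr in ensemble.frames:
        contacts, _ = count_contacts(fr, ensemble.peptide_chain,
                                     ensemble.receptor_chains, core_resnums,
                                     cutoff=cutoff,
                                     include_hydrogens=include_hydrogens)
        hbonds, _ = count_backbone_hbonds(fr, ensemble.peptide_chain,
                                          ensemble.receptor_chains,
                                          core_resnums, criteria=criteria)
        for k in range(CORE_LENGTH):
            rows.append((fr.index, k + 1, core_seq[k], int(hbonds[k]),
                         int(contacts[k]),
                         np.nan if fr.energy is None else fr.energy))
    df = pd.DataFrame(rows, columns=["frame", "core_position", "amino_acid",
                                     "hbonds", "contacts", "energy"])
    return ObservableTable(run_id=run_id, df=df, n_frames=ensemble.n_frames)


def write_observable_table(table: ObservableTable, path) -> None:
    out = table.df.copy()
    out.insert(0, "run_id", table.run_id)
    out.to_csv(path, sep="\t", index=False)


def read_observable_tables(path) -> list[ObservableTable]:
    """Read one TSV possibly holding several runs (run_id column)."""
    df = pd.read_csv(path, sep="\t")
    tables = []
    for run_id, sub in df.groupby("run_id", sort=False):
        sub = sub.drop(columns=["run_id"]).reset_index(drop=True)
        tables.append(ObservableTable(run_id=str(run_id), df=sub,
                                      n_frames=sub["frame"].nunique()))
    return tables


@dataclass(frozen=True)
class EnsembleSummary:
    """Mean ± SD over frames of the per-frame core-region totals."""

    run_id: str
    mean_contacts: float
    sd_contacts: float
    mean_hbonds: float
    sd_hbonds: float


def summarize_ensemble(table: ObservableTable) -> EnsembleSummary:
    """Mean and population SD across frames of the per-frame totals."""
    if table.n_frames < 2:
        raise ValidationError("summary needs >= 2 frames for an SD")
    c = table.frame_totals("contacts")
    h = table.frame_totals("hbonds")
    return EnsembleSummary(
        run_id=table.run_id,
        mean_contacts=float(c.mean()), sd_contacts=float(c.std(ddof=0)),
        mean_hbonds=float(h.mean()), sd_hbonds=float(h.std(ddof=0)),
    )


def grand_average(per_structure_means: Sequence[float]) -> float:
    """Arithmetic mean over ensembles of per-ensemble means, to 1 decimal."""
    vals = np.asarray(per_structure_means, dtype=float)
    if vals.size == 0:
        raise ParameterError("grand average needs >= 1 value")
    return float(round(vals.mean(), 1))
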