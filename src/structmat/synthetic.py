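"""Synthetic inputs with analytically known ground truth.

Three generators cover the pipeline end to end without any external data:

* :func:`make_toy_complex` builds a multi-model ensemble of a peptide laid
  along a rigid two-chain "groove" scaffold.  Receptor probe atoms are placed
  at exact distances so that every core position realizes a planted number of
  non-bonded contacts, and acceptor probes with compliant geometry realize a
  planted number of backbone hydrogen bonds.  Frames are the base geometry
  plus bounded Gaussian jitter, small enough (margin audit) that no planted
  criterion can flip; the exact expected per-position counts are returned
  alongside the ensemble.
* :func:`make_planted_cohort` draws peptides position-wise from the
  frequencies exp(-E) of a planted scoring matrix and assigns binding
  activities log-linear in the planted core score (plus optional noise),
  spanning roughly 1-10,000 nM.
* :func:`make_score_tables` emulates per-frame score tables of six external
  scoring functions whose mean-score differences carry the experimental sign
  with a stated per-function probability.

The toy scaffold is an extended, strictly linear backbone; it makes no claim
of structural realism.  Every generator is bit-reproducible under its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ParameterError, ValidationError
from .matrices import AA_ALPHABET, AA_INDEX, CORE_LENGTH, N_AA
from .observables import HBondCriteria, place_amide_hydrogen
from .prediction import MutationPair, experimental_sign
from .structure_io import (
    AtomRecord,
    CoreAssignment,
    EnsembleComplex,
    Frame,
    ONE_TO_THREE,
)

# Scaffold geometry constants (Å)
_SPACING = 8.0          # inter-residue spacing along x
_CONTACT_DIST = 3.4     # probe-to-anchor distance (cutoff 4.0, margin 0.6)
_ACCEPTOR_DIST = 2.9    # donor-acceptor distance for planted hydrogen bonds
_ACCEPTOR_CONE_DEG = 18.0
_MAX_CONTACTS = 20
_MAX_HBONDS = 4
_MAX_JITTER_SD = 0.03
_CUTOFF = 4.0


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for one toy peptide-receptor ensemble."""

    n_frames: int = 1
    peptide_sequence: str = "A" * CORE_LENGTH
    core_start: int = 0
    planted_contacts: tuple[int, ...] = (0,) * CORE_LENGTH
    planted_hbonds: tuple[int, ...] = (0,) * CORE_LENGTH
    jitter_sd: float = 0.0
    seed: int = 0
    with_energies: bool = True
    n_decoys: int = 0  # near-miss acceptors that must not count

    def __post_init__(self):
        object.__setattr__(self, "planted_contacts", tuple(self.planted_contacts))
        object.__setattr__(self, "planted_hbonds", tuple(self.planted_hbonds))
        if self.n_frames < 1:
            raise ParameterError("need >= 1 frame")
        if not (CORE_LENGTH <= len(self.peptide_sequence) <= 15):
            raise ParameterError("peptide length must be 9..15")
        bad = set(self.peptide_sequence) - set(ONE_TO_THREE)
        if bad:
            raise ParameterError(f"non-standard letters {sorted(bad)}")
        if len(self.planted_contacts) != CORE_LENGTH or \
                len(self.planted_hbonds) != CORE_LENGTH:
            raise ParameterError("planted counts must have 9 entries")
        if any(c < 0 or c > _MAX_CONTACTS for c in self.planted_contacts):
            raise CapacityError(
                f"planted contacts must be 0..{_MAX_CONTACTS} per position")
        if any(h < 0 or h > _MAX_HBONDS for h in self.planted_hbonds):
            raise CapacityError(
                f"planted hydrogen bonds must be 0..{_MAX_HBONDS} per position")
        if not 0.0 <= self.jitter_sd <= _MAX_JITTER_SD:
            raise CapacityError(
                f"jitter_sd must be within [0, {_MAX_JITTER_SD}] Å to keep all "
                "planted criteria stable under jitter")
        for k, h in enumerate(self.planted_hbonds):
            if h > 0 and self.core_start + k == 0:
                raise CapacityError(
                    "cannot plant hydrogen bonds at the chain-start residue "
                    "(no preceding carbonyl: the amide cannot donate)")


@dataclass(frozen=True)
class ToyComplexTruth:
    """Exact expected per-core-position counts for a toy ensemble."""

    contacts: np.ndarray  # (9,) int
    hbonds: np.ndarray    # (9,) int


def _backbone(i: int) -> dict[str, np.ndarray]:
    x0 = _SPACING * i
    return {
        "N": np.array([x0, 0.0, 0.0]),
        "CA": np.array([x0 + 1.0, 2.0, 0.0]),
        "C": np.array([x0 + 3.0, 0.0, 0.0]),
        "O": np.array([x0 + 3.0, -1.23, 0.0]),
        "CB": np.array([x0 + 1.0, 2.0, -3.0]),  # scaffold anchor, all residues
    }


def _amide_axis(i: int) -> np.ndarray:
    """Unit vector from N toward the (geometrically placed) amide H."""
    bb = _backbone(i)
    prev_c = _backbone(i - 1)["C"]
    h = place_amide_hydrogen(bb["N"], bb["CA"], prev_c)
    return (h - bb["N"]) / np.linalg.norm(h - bb["N"])


def _cone_directions(axis: np.ndarray, beta_deg: float, n: int) -> list[np.ndarray]:
    """n unit vectors at angle beta from axis (first one on-axis when n=1)."""
    if n == 1:
        return [axis]
    e1 = np.cross(axis, np.array([0.0, 0.0, 1.0]))
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    beta = np.radians(beta_deg)
    psis = [np.radians(p) for p in (90.0, 270.0, 0.0, 180.0)][:n]
    return [np.cos(beta) * axis + np.sin(beta) * (np.cos(p) * e1 + np.sin(p) * e2)
            for p in psis]


def _build_base_geometry(spec: ToyComplexSpec):
    """Base (jitter-free) atoms: peptide chain C, receptor chains A (contact
    probes) and B (acceptor probes + decoys)."""
    atoms: list[AtomRecord] = []
    length = len(spec.peptide_sequence)
    for i, aa in enumerate(spec.peptide_sequence):
        bb = _backbone(i)
        resname = ONE_TO_THREE[aa]
        for name in ("N", "CA", "C", "O", "CB"):
            element = name[0]
            atoms.append(AtomRecord("C", i + 1, resname, name, element, bb[name]))

    probe_resnum = itertools.count(1)
    contact_atoms: list[AtomRecord] = []
    golden = np.radians(137.5)
    for k in range(CORE_LENGTH):
        i = spec.core_start + k
        anchor = _backbone(i)["CB"]
        n_probes = spec.planted_contacts[k]
        phi = np.radians(25.0)
        for m in range(n_probes):
            theta = golden * m
            d = np.array([np.sin(phi) * np.cos(theta),
                          np.sin(phi) * np.sin(theta),
                          -np.cos(phi)])
            pos = anchor + _CONTACT_DIST * d
            contact_atoms.append(AtomRecord("A", next(probe_resnum), "PRB",
                                            f"CP{m + 1}", "C", pos))

    acceptor_atoms: list[AtomRecord] = []
    acc_resnum = itertools.count(1)
    for k in range(CORE_LENGTH):
        i = spec.core_start + k
        n_acc = spec.planted_hbonds[k]
        if n_acc == 0:
            continue
        axis = _amide_axis(i)
        n_pos = _backbone(i)["N"]
        for m, d in enumerate(_cone_directions(axis, _ACCEPTOR_CONE_DEG, n_acc)):
            pos = n_pos + _ACCEPTOR_DIST * d
            acceptor_atoms.append(AtomRecord("B", next(acc_resnum), "PRB",
                                             f"OP{m + 1}", "O", pos))
    # decoys: acceptors along the donor axis but beyond every distance
    # criterion; they still land within the contact cutoff of nothing
    for m in range(spec.n_decoys):
        i = spec.core_start + 1 + (m % max(1, CORE_LENGTH - 1))
        axis = _amide_axis(i)
        pos = _backbone(i)["N"] + 5.2 * axis
        acceptor_atoms.append(AtomRecord("B", next(acc_resnum), "PRB",
                                         "OPD", "O", pos))

    return atoms, contact_atoms, acceptor_atoms


def _audit_and_truth(spec: ToyComplexSpec, pep_atoms: list[AtomRecord],
                     receptor_atoms: list[AtomRecord]) -> ToyComplexTruth:
    """Exact per-position counts at base geometry, with a jitter margin audit.

    Per-component jitter is clipped at 3 sigma, so an atom moves at most
    3*sqrt(3)*sigma and any pairwise distance changes by at most twice that;
    a margin of 12*sigma on every distance criterion therefore guarantees no
    count can flip in any jittered frame.
    """
    margin = 12.0 * spec.jitter_sd + 1e-9
    crit = HBondCriteria()
    core_resnums = [spec.core_start + k + 1 for k in range(CORE_LENGTH)]
    by_res: dict[int, list[AtomRecord]] = {}
    for a in pep_atoms:
        by_res.setdefault(a.residue_number, []).append(a)

    contacts = np.zeros(CORE_LENGTH, dtype=int)
    for k, rn in enumerate(core_resnums):
        for pa in by_res[rn]:
            for ra in receptor_atoms:
                d = float(np.linalg.norm(ra.position - pa.position))
                if abs(d - _CUTOFF) <= margin:
                    raise CapacityError(
                        f"probe at {d:.3f} Å of core position {k + 1} sits "
                        f"within {margin:.3f} Å of the contact cutoff; reduce "
                        "jitter_sd or planted counts")
                if d <= _CUTOFF:
                    contacts[k] += 1

    hbonds = np.zeros(CORE_LENGTH, dtype=int)
    acceptors = [a for a in receptor_atoms if a.element == "O"]
    for k, rn in enumerate(core_resnums):
        i = rn - 1  # 0-based residue index
        if i == 0:
            continue
        n_pos = _backbone(i)["N"]
        h_pos = place_amide_hydrogen(n_pos, _backbone(i)["CA"],
                                     _backbone(i - 1)["C"])
        for acc in acceptors:
            d_na = float(np.linalg.norm(acc.position - n_pos))
            d_ha = float(np.linalg.norm(acc.position - h_pos))
            u = n_pos - h_pos
            v = acc.position - h_pos
            ang = float(np.degrees(np.arccos(np.clip(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                -1.0, 1.0))))
            passes = (d_na <= crit.d_a_max and d_ha <= crit.h_a_max
                      and ang >= crit.theta_min_deg)
            if passes:
                if (d_na > crit.d_a_max - margin or d_ha > crit.h_a_max - margin
                        or ang < crit.theta_min_deg + 5.0):
                    raise CapacityError(
                        "planted hydrogen bond passes without a jitter-safe margin")
                hbonds[k] += 1
            else:
                ok = (d_na > crit.d_a_max + margin
                      or d_ha > crit.h_a_max + margin
                      or ang < crit.theta_min_deg - 5.0)
                if not ok:
                    raise CapacityError(
                        "non-bonding acceptor fails criteria without a "
                        "jitter-safe margin")

    if not np.array_equal(hbonds, np.array(spec.planted_hbonds)):
        raise CapacityError(
            f"geometry realizes hydrogen bonds {hbonds.tolist()} instead of "
            f"planted {list(spec.planted_hbonds)}")
    if sum(spec.planted_hbonds) == 0 and spec.n_decoys == 0:
        assert np.array_equal(contacts, np.array(spec.planted_contacts)), \
            "contact probes must realize planted counts exactly"
    return ToyComplexTruth(contacts=contacts, hbonds=hbonds)


def make_toy_complex(spec: ToyComplexSpec) -> tuple[EnsembleComplex, ToyComplexTruth]:
    """Build a toy ensemble and its exact expected observable counts.

    The returned truth gives, per core position, the contact count (planted
    probes plus the audited extra pairs contributed by hydrogen-bond probe
    atoms, which necessarily sit within the contact cutoff) and the hydrogen
    bond count (exactly the planted number).  Raises :class:`CapacityError`
    when the request cannot be realized with jitter-safe margins.
    """
    pep_atoms, contact_atoms, acceptor_atoms = _build_base_geometry(spec)
    receptor_atoms = contact_atoms + acceptor_atoms
    truth = _audit_and_truth(spec, pep_atoms, receptor_atoms)

    base = pep_atoms + receptor_atoms
    base_xyz = np.array([a.position for a in base])
    rng = np.random.default_rng(spec.seed)
    frames: list[Frame] = []
    for f in range(spec.n_frames):
        if spec.jitter_sd > 0:
            jitter = rng.normal(0.0, spec.jitter_sd, size=base_xyz.shape)
            np.clip(jitter, -3 * spec.jitter_sd, 3 * spec.jitter_sd, out=jitter)
            xyz = base_xyz + jitter
        else:
            xyz = base_xyz
        energy = float(rng.normal()) if spec.with_energies else None
        atoms = tuple(
            AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                       a.atom_name, a.element, xyz[j])
            for j, a in enumerate(base))
        frames.append(Frame(index=f, atoms=atoms, energy=energy))

    core = CoreAssignment(peptide_sequence=spec.peptide_sequence,
                          core_start=spec.core_start)
    ensemble = EnsembleComplex(frames=frames, peptide_chain="C",
                               receptor_chains=frozenset({"A", "B"}), core=core)
    return ensemble, truth


# ---------------------------------------------------------------------------
# Planted peptide cohorts
# ---------------------------------------------------------------------------

ACTIVITY_SPAN_LOG = float(np.log(10_000.0))  # activities span ~1..10,000 nM


@dataclass(frozen=True)
class PlantedCohortSpec:
    """Recipe for a peptide cohort whose activities follow a planted matrix."""

    n_peptides: int
    planted_E: np.ndarray
    activity_noise_sd: float = 0.0  # log-nM scale
    activity_slope: float = 1.0     # 0 => activities independent of sequence
    seed: int = 0

    def __post_init__(self):
        E = np.asarray(self.planted_E, dtype=float)
        if E.shape != (CORE_LENGTH, N_AA):
            raise ValidationError("planted_E must be 9x20")
        norms = np.exp(-E).sum(axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("planted_E must satisfy sum_j exp(-E_ij) = 1")
        object.__setattr__(self, "planted_E", E)
        if self.n_peptides < 1:
            raise ParameterError("need >= 1 peptide")
        if self.activity_noise_sd < 0:
            raise ParameterError("noise SD must be non-negative")


@dataclass(frozen=True)
class CohortTruth:
    planted_E: np.ndarray
    scores: np.ndarray       # planted core score per peptide
    log_activity_clean: np.ndarray


def random_planted_E(seed: int = 0, ratio: float = 0.85) -> np.ndarray:
    """A legal planted matrix with geometric per-position preference profiles.

    At each position the 20 amino acids receive a random preference order and
    frequencies proportional to ``ratio**rank`` (rank 0 = most preferred), so
    planted energies are uniformly log-spaced — a strongly peaked profile of
    the kind anchor pockets impose, with every residue type attainable.
    """
    rng = np.random.default_rng(seed)
    E = np.zeros((CORE_LENGTH, N_AA))
    for i in range(CORE_LENGTH):
        ranks = rng.permutation(N_AA)
        f = ratio ** ranks
        E[i] = -np.log(f / f.sum())
    return E


def _log_activity(score: float, E: np.ndarray, slope: float) -> float:
    s_min = float(E.min(axis=1).sum())
    s_max = float(E.max(axis=1).sum())
    if s_max == s_min:
        return 0.0
    return slope * ACTIVITY_SPAN_LOG * (score - s_min) / (s_max - s_min)


def planted_core_score(E: np.ndarray, core: str) -> float:
    return float(sum(E[i, AA_INDEX[aa]] for i, aa in enumerate(core)))


def make_planted_cohort(spec: PlantedCohortSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw peptides from exp(-planted_E) and assign log-linear activities."""
    rng = np.random.default_rng(spec.seed)
    E = spec.planted_E
    freq = np.exp(-E)
    letters = np.array(list(AA_ALPHABET))
    idx = np.stack([rng.choice(N_AA, size=spec.n_peptides,
                               p=freq[i] / freq[i].sum())
                    for i in range(CORE_LENGTH)], axis=1)
    seqs = ["".join(row) for row in letters[idx]]
    scores = E[np.arange(CORE_LENGTH), idx].sum(axis=1)
    clean = [_log_activity(float(s), E, spec.activity_slope) for s in scores]
    noise = rng.normal(0.0, spec.activity_noise_sd, size=spec.n_peptides) \
        if spec.activity_noise_sd > 0 else np.zeros(spec.n_peptides)
    activities = np.exp(np.array(clean) + noise)
    df = pd.DataFrame({"sequence": seqs, "activity_nM": activities,
                       "core_start": 0})
    truth = CohortTruth(planted_E=E, scores=np.array(scores),
                        log_activity_clean=np.array(clean))
    return df, truth


def make_mutation_pairs(planted_E: np.ndarray, n_pairs: int,
                        activity_noise_sd: float = 0.0, seed: int = 0,
                        min_delta: float = 0.5,
                        activity_slope: float = 1.0) -> list[MutationPair]:
    """Single-substitution 9-mer pairs with activities from the planted model.

    The mutated amino acid is drawn among those whose planted energy differs
    from the wild type's by at least ``min_delta`` at that position, so the
    planted effect size is bounded away from zero.
    """
    E = np.asarray(planted_E, dtype=float)
    rng = np.random.default_rng(seed)
    freq = np.exp(-E)
    letters = list(AA_ALPHABET)
    pairs: list[MutationPair] = []
    attempts = 0
    while len(pairs) < n_pairs:
        attempts += 1
        if attempts > 100 * n_pairs:
            raise CapacityError(
                f"cannot find enough substitutions with |dE| >= {min_delta}")
        idx = [rng.choice(N_AA, p=freq[i] / freq[i].sum())
               for i in range(CORE_LENGTH)]
        wt_seq = "".join(letters[j] for j in idx)
        pos = int(rng.integers(CORE_LENGTH))
        wt_j = idx[pos]
        candidates = [j for j in range(N_AA)
                      if j != wt_j and abs(E[pos, j] - E[pos, wt_j]) >= min_delta]
        if not candidates:
            continue
        mut_j = int(rng.choice(candidates))
        mut_seq = wt_seq[:pos] + letters[mut_j] + wt_seq[pos + 1:]
        eps = rng.normal(0.0, activity_noise_sd, size=2) \
            if activity_noise_sd > 0 else np.zeros(2)
        act_wt = float(np.exp(_log_activity(planted_core_score(E, wt_seq), E,
                                            activity_slope) + eps[0]))
        act_mut = float(np.exp(_log_activity(planted_core_score(E, mut_seq), E,
                                             activity_slope) + eps[1]))
        pairs.append(MutationPair(
            pair_id=f"pair{len(pairs):04d}", wt_sequence=wt_seq,
            mut_sequence=mut_seq, core_position=pos + 1,
            activity_wt=act_wt, activity_mut=act_mut))
    return pairs


def make_cohort_ensembles(cohort: pd.DataFrame, planted_E: np.ndarray,
                          seed: int = 0, n_frames: int = 1, jitter_sd: float = 0.0
                          ) -> Iterator[tuple[EnsembleComplex, ToyComplexTruth]]:
    """One toy ensemble per cohort peptide, with per-position contact counts
    decreasing one-by-one with the planted preference rank of the residue at
    that position (interaction counts track binding preference; the most
    preferred residue realizes 20 probes, the least preferred 1)."""
    E = np.asarray(planted_E, dtype=float)
    ranks = np.argsort(np.argsort(E, axis=1), axis=1)  # 0 = most preferred
    counts_by_cell = N_AA - ranks
    for i, row in enumerate(cohort.itertuples(index=False)):
        seq = row.sequence
        counts = tuple(int(counts_by_cell[k, AA_INDEX[aa]])
                       for k, aa in enumerate(seq))
        spec = ToyComplexSpec(n_frames=n_frames, peptide_sequence=seq,
                              core_start=0, planted_contacts=counts,
                              planted_hbonds=(0,) * CORE_LENGTH,
                              jitter_sd=jitter_sd, seed=seed + i)
        yield make_toy_complex(spec)


# ---------------------------------------------------------------------------
# Synthetic external score tables
# ---------------------------------------------------------------------------

DEFAULT_FUNCTIONS = ("sf1", "sf2", "sf3", "sf4", "sf5", "sf6")


def make_score_tables(pairs: Sequence[MutationPair],
                      per_function_accuracy: Sequence[float],
                      frames_per_peptide: int = 10, seed: int = 0,
                      effect: float = 1.0, frame_noise_sd: float = 0.1
                      ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-frame score tables whose per-function mean differences carry the
    experimental sign with the stated probabilities (orientation: lower =
    better for every function)."""
    accs = list(per_function_accuracy)
    if any(not 0.0 <= p <= 1.0 for p in accs):
        raise ParameterError("accuracies must lie in [0, 1]")
    functions = [f"sf{i + 1}" for i in range(len(accs))]
    rng = np.random.default_rng(seed)
    rows = []
    for pair in pairs:
        es = experimental_sign(pair)
        for fn, p in zip(functions, accs):
            sign = es if rng.random() < p else -es
            for role, mean in (("wt", 0.0), ("mut", effect * sign)):
                scores = mean + rng.normal(0.0, frame_noise_sd,
                                           size=frames_per_peptide)
                for fr, s in enumerate(scores):
                    rows.append((pair.pair_id, role, fn, fr, float(s)))
    df = pd.DataFrame(rows, columns=["pair_id", "role", "function",
                                     "frame", "score"])
    return df, {fn: "asc" for fn in functions}
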