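"""Position-specific scoring matrices from structural observables.

The central objects are the 9x20 grids O (average observable per core
position i and amino acid j) and E (scoring energy).  O accumulates per-frame
counts over simulation runs,

    O_ij = (1/Nf) * sum_alpha sum_f o_ij^{alpha,f},

where Nf is the number of selected frames per run (identical across runs) and
alpha indexes runs — one run per peptide, so the dataset's amino-acid
frequencies weight O implicitly.  The scoring energy is the position-wise
normalized log transform

    E_ij = -ln( O_ij / sum_j O_ij ),

so that sum_j exp(-E_ij) = 1 at every position.  Zero cells receive a small
pseudocount before the transform to keep E finite.

The module also provides the sequence-side machinery used to assemble
peptide datasets: sliding 9-mer window scoring under a sequence PSSM,
two-method core consensus, and the flank filter (a peptide is discarded when
either terminus would require adding more than two residues to the template).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlphabetError,
    MissingDataError,
    NormalizationError,
    ParameterError,
    ValidationError,
)
from .observables import ObservableTable
from .structure_io import CORE_LENGTH, EnsembleComplex

#: Column order of every 9x20 grid.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA = len(AA_ALPHABET)


class Strategy(str, Enum):
    """Frame-selection strategies for matrix construction."""

    ALL = "all"
    LAST_HALF = "last_half"
    BEST_ENERGY_HALF = "best_energy_half"
    BEST_ENERGY_ONE = "best_energy_one"


@dataclass(frozen=True)
class FrameSelection:
    strategy: Strategy
    selected_indices: tuple[int, ...]

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)


def _select(frame_indices: np.ndarray, energies: np.ndarray | None,
            strategy: Strategy) -> tuple[int, ...]:
    n = len(frame_indices)
    if strategy == Strategy.ALL:
        return tuple(int(i) for i in frame_indices)
    if strategy == Strategy.LAST_HALF:
        k = -(-n // 2)  # ceil
        return tuple(int(i) for i in frame_indices[n - k:])
    if energies is None:
        raise MissingDataError(
            f"strategy '{strategy.value}' requires per-frame energies")
    order = np.argsort(energies, kind="stable")  # ties: lower frame index wins
    if strategy == Strategy.BEST_ENERGY_ONE:
        chosen = order[:1]
    else:  # BEST_ENERGY_HALF
        chosen = order[:-(-n // 2)]
    return tuple(int(frame_indices[i]) for i in sorted(chosen))


def select_frames(ensemble: EnsembleComplex, strategy: Strategy | str) -> FrameSelection:
    """Select frames of an ensemble under one of the four strategies.

    ``all`` keeps every frame; ``last_half`` the last ceil(Nf/2) in order;
    ``best_energy_half`` the ceil(Nf/2) lowest-energy frames (energy ties
    broken toward the lower frame index); ``best_energy_one`` the single
    lowest-energy frame.
    """
    strategy = Strategy(strategy)
    idx = np.array([fr.index for fr in ensemble.frames])
    return FrameSelection(strategy,
                          _select(idx, ensemble.energies(), strategy))


def select_frames_from_table(table: ObservableTable,
                             strategy: Strategy | str) -> FrameSelection:
    """Same selection, driven by an observable table's energy column."""
    strategy = Strategy(strategy)
    idx = np.sort(table.df["frame"].unique())
    return FrameSelection(strategy, _select(idx, table.frame_energies(), strategy))


# ---------------------------------------------------------------------------
# Accumulation (Eq. 1) and matrix construction (Eq. 2)
# ---------------------------------------------------------------------------

def accumulate(tables: Sequence[ObservableTable], observable: str,
               selections: Sequence[FrameSelection]) -> np.ndarray:
    """Average the observable over runs and selected frames into O (9x20).

    Nf is the per-run selected-frame count and must be identical across runs
    (differing counts raise :class:`NormalizationError`).  Cells never seen
    in any run stay 0.
    """
    if observable not in ("hbonds", "contacts"):
        raise ParameterError(f"unknown observable '{observable}'")
    if len(tables) != len(selections):
        raise ParameterError("one selection per observable table required")
    if not tables:
        raise ParameterError("need >= 1 run to accumulate")
    nf = {sel.n_selected for sel in selections}
    if len(nf) != 1:
        raise NormalizationError(
            f"runs have differing selected-frame counts: {sorted(nf)}")
    nf = nf.pop()
    if nf == 0:
        raise NormalizationError("empty frame selection")

    O = np.zeros((CORE_LENGTH, N_AA), dtype=float)
    for table, sel in zip(tables, selections):
        sub = table.df[table.df["frame"].isin(sel.selected_indices)]
        grouped = sub.groupby(["core_position", "amino_acid"])[observable].sum()
        for (pos, aa), total in grouped.items():
            if aa not in AA_INDEX:
                raise AlphabetError(f"run {table.run_id}: non-standard letter '{aa}'")
            O[int(pos) - 1, AA_INDEX[aa]] += total / nf
    return O


def energies_from_observables(O: np.ndarray,
                              pseudocount: float | np.ndarray = 0.0) -> np.ndarray:
    """E = -ln((O + pc) / row_sum(O + pc)), row-wise over positions.

    Works for any (L, K) grid; ``pseudocount`` may be a scalar or a per-row
    vector.
    """
    O = np.asarray(O, dtype=float)
    if np.any(O < 0):
        raise ValidationError("observable averages must be non-negative")
    pc = np.asarray(pseudocount, dtype=float)
    if pc.ndim == 1:
        pc = pc[:, None]
    Op = O + pc
    row_sums = Op.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        bad = int(np.where(Op.sum(axis=1) <= 0)[0][0])
        raise NormalizationError(
            f"position {bad + 1} has no observable mass (all-zero row with "
            "zero pseudocount)")
    if np.any(Op <= 0):
        raise NormalizationError(
            "zero cells remain; use a positive pseudocount to keep E finite")
    return -np.log(Op / row_sums)


DEFAULT_PSEUDOCOUNT_SCALE = 1e-6


@dataclass
class StructMatrix:
    """A 9x20 structural scoring matrix (observable averages + energies)."""

    observable_name: str
    strategy: Strategy
    O: np.ndarray
    E: np.ndarray
    pseudocount: np.ndarray  # per-position value actually applied

    def __post_init__(self):
        self.O = np.asarray(self.O, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.pseudocount = np.atleast_1d(np.asarray(self.pseudocount, dtype=float))
        if self.O.shape != (CORE_LENGTH, N_AA) or self.E.shape != (CORE_LENGTH, N_AA):
            raise ValidationError("O and E must be 9x20 grids")
        if not np.all(np.isfinite(self.E)):
            raise ValidationError("E must be finite everywhere")
        norms = np.exp(-self.E).sum(axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("sum_j exp(-E_ij) must equal 1 at every position")

    def frequencies(self) -> np.ndarray:
        """Position-normalized frequencies exp(-E); columns of a logo."""
        return np.exp(-self.E)

    def energy(self, core_position: int, amino_acid: str) -> float:
        if not 1 <= core_position <= CORE_LENGTH:
            raise ParameterError(f"core position {core_position} outside 1..9")
        if amino_acid not in AA_INDEX:
            raise AlphabetError(f"non-standard letter '{amino_acid}'")
        return float(self.E[core_position - 1, AA_INDEX[amino_acid]])


def build_matrix(O: np.ndarray, pseudocount: float | None = None,
                 observable_name: str = "hbonds",
                 strategy: Strategy | str = Strategy.ALL) -> StructMatrix:
    """Build a :class:`StructMatrix` from accumulated observables.

    With ``pseudocount=None`` each position uses 1e-6 times its largest cell,
    keeping E finite where some amino acids were never observed without
    perturbing the observed cells.
    """
    O = np.asarray(O, dtype=float)
    if O.shape != (CORE_LENGTH, N_AA):
        raise ValidationError("O must be a 9x20 grid")
    if pseudocount is None:
        row_max = O.max(axis=1)
        if np.any(row_max <= 0):
            bad = int(np.where(row_max <= 0)[0][0])
            raise NormalizationError(
                f"position {bad + 1} has no positive cell; cannot derive an "
                "automatic pseudocount")
        pc = DEFAULT_PSEUDOCOUNT_SCALE * row_max
    else:
        pc = np.full(CORE_LENGTH, float(pseudocount))
    E = energies_from_observables(O, pc)
    return StructMatrix(observable_name=observable_name,
                        strategy=Strategy(strategy), O=O, E=E, pseudocount=pc)


def score_core(matrix: StructMatrix, core: str) -> float:
    """Whole-core score sum_i E[i, core[i]]; lower = predicted better binder."""
    if len(core) != CORE_LENGTH:
        raise ParameterError(f"core must have 9 residues, got {len(core)}")
    return float(sum(matrix.energy(i + 1, aa) for i, aa in enumerate(core)))


# ---------------------------------------------------------------------------
# Sequence-side machinery
# ---------------------------------------------------------------------------

@dataclass
class SequencePSSM:
    """A published 9x20 sequence scoring matrix (higher = more probable)."""

    scores: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (CORE_LENGTH, N_AA):
            raise ValidationError("sequence PSSM must be a 9x20 grid")

    def score_window(self, window: str) -> float:
        try:
            return float(sum(self.scores[i, AA_INDEX[aa]]
                             for i, aa in enumerate(window)))
        except KeyError as exc:
            raise AlphabetError(f"non-standard letter {exc} in window") from exc


class CoreWindow(NamedTuple):
    window_start: int
    window: str
    score: float


def predict_core(pssm: SequencePSSM, sequence: str) -> list[CoreWindow]:
    """Score every 9-mer window; ranked descending, ties to the smaller start."""
    if len(sequence) < CORE_LENGTH:
        raise ParameterError(
            f"sequence length {len(sequence)} < core length {CORE_LENGTH}")
    windows = [CoreWindow(s, sequence[s:s + CORE_LENGTH],
                          pssm.score_window(sequence[s:s + CORE_LENGTH]))
               for s in range(len(sequence) - CORE_LENGTH + 1)]
    return sorted(windows, key=lambda w: (-w.score, w.window_start))


@dataclass(frozen=True)
class ConsensusResult:
    accepted: bool
    reason: str
    core: CoreWindow | None = None


def consensus_core(pred_a: CoreWindow, pred_b: CoreWindow) -> ConsensusResult:
    """Accept iff both methods' top windows agree in start and sequence."""
    if pred_a.window_start == pred_b.window_start and pred_a.window == pred_b.window:
        return ConsensusResult(True, "identical top-ranked cores", pred_a)
    return ConsensusResult(
        False,
        f"top cores disagree: start {pred_a.window_start} '{pred_a.window}' vs "
        f"start {pred_b.window_start} '{pred_b.window}'")


def flank_filter(core_start: int, peptide_length: int,
                 template_core_start: int, template_length: int,
                 max_added: int = 2) -> bool:
    """Accept a peptide whose flanks fit the template with <= ``max_added``
    appended residues at each terminus (cores assumed aligned)."""
    for v in (core_start, peptide_length, template_core_start, template_length):
        if v < 0:
            raise ParameterError("lengths and offsets must be non-negative")
    if core_start + CORE_LENGTH > peptide_length:
        raise ParameterError("query core window exceeds peptide length")
    if template_core_start + CORE_LENGTH > template_length:
        raise ParameterError("template core window exceeds template length")
    added_n = max(0, core_start - template_core_start)
    q_c = peptide_length - core_start - CORE_LENGTH
    t_c = template_length - template_core_start - CORE_LENGTH
    added_c = max(0, q_c - t_c)
    return added_n <= max_added and added_c <= max_added


def export_frequency_logo(source: StructMatrix | Sequence[str]) -> pd.DataFrame:
    """Column-normalized frequency table (positions x 20) in logo-ready form.

    For a :class:`StructMatrix` the frequencies are exp(-E); for an aligned
    peptide set they are per-column letter frequencies.
    """
    if isinstance(source, StructMatrix):
        freq = source.frequencies()
        index = [f"pos{i+1}" for i in range(CORE_LENGTH)]
    else:
        peptides = list(source)
        if not peptides:
            raise ParameterError("empty peptide set")
        length = len(peptides[0])
        if any(len(p) != length for p in peptides):
            raise ValidationError("peptides must be aligned to equal length")
        freq = np.zeros((length, N_AA))
        for p in peptides:
            for i, aa in enumerate(p):
                if aa not in AA_INDEX:
                    raise AlphabetError(f"non-standard letter '{aa}'")
                freq[i, AA_INDEX[aa]] += 1
        freq /= len(peptides)
        index = [f"pos{i+1}" for i in range(length)]
    return pd.DataFrame(freq, index=index, columns=list(AA_ALPHABET))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _grid_to_tsv(grid: np.ndarray, path: Path) -> None:
    pd.DataFrame(grid, index=[f"pos{i+1}" for i in range(grid.shape[0])],
                 columns=list(AA_ALPHABET)).to_csv(path, sep="\t",
                                                   index_label="position")


def _grid_from_tsv(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(AA_ALPHABET):
        raise ValidationError(f"{path}: columns must be the 20 standard letters "
                              "in alphabetical order")
    return df.to_numpy(dtype=float)


def write_matrix(matrix: StructMatrix, prefix: str | Path) -> None:
    """Write PREFIX.O.tsv, PREFIX.E.tsv and PREFIX.json (metadata)."""
    prefix = Path(prefix)
    _grid_to_tsv(matrix.O, Path(str(prefix) + ".O.tsv"))
    _grid_to_tsv(matrix.E, Path(str(prefix) + ".E.tsv"))
    meta = {
        "observable": matrix.observable_name,
        "strategy": matrix.strategy.value,
        "pseudocount": [float(v) for v in matrix.pseudocount],
    }
    Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_matrix(prefix: str | Path) -> StructMatrix:
    prefix = Path(prefix)
    meta = json.loads(Path(str(prefix) + ".json").read_text())
    return StructMatrix(
        observable_name=meta["observable"],
        strategy=Strategy(meta["strategy"]),
        O=_grid_from_tsv(Path(str(prefix) + ".O.tsv")),
        E=_grid_from_tsv(Path(str(prefix) + ".E.tsv")),
        pseudocount=np.asarray(meta["pseudocount"], dtype=float),
    )


def read_pssm(path: str | Path, source_label: str = "") -> SequencePSSM:
    """Read a sequence PSSM from the same 9x20 TSV layout."""
    return SequencePSSM(scores=_grid_from_tsv(Path(path)),
                        source_label=source_label or str(path))


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide dataset: TSV with columns sequence, activity_nM
    (optional core_start), or FASTA (sequences only)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        return pd.DataFrame({"sequence": seqs})
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns:
        raise ValidationError(f"{path}: peptide table needs a 'sequence' column")
    return df
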