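"""Sign prediction of single-point-mutation activity differences.

Binding activity is nM-like (lower = stronger binder).  For a pair of
peptides differing at one core position, the experimental sign is
sign(activity_mut - activity_wt): +1 means the mutation weakens binding.
A structural matrix predicts the same sign as sign(E[mut] - E[wt]) at the
mutated position, since E is a -ln probability (larger = less favourable).

A pair evaluated under the external-scoring consensus rule counts as a match
when at least ``min_agree`` (default 3) of the six scoring functions' mean
per-frame score differences carry the experimental sign.  Two methods'
per-pair matches combine by elementwise OR ("conditional or").  Match rates
are summarized with a with-replacement bootstrap over pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .matrices import StructMatrix
from .structure_io import CORE_LENGTH, CoreAssignment

SCORE_TABLE_COLUMNS = ["pair_id", "role", "function", "frame", "score"]


@dataclass(frozen=True)
class MutationPair:
    """Two peptides differing at exactly one core position, with activities."""

    pair_id: str
    wt_sequence: str
    mut_sequence: str
    core_position: int  # 1..9
    activity_wt: float
    activity_mut: float
    core_start: int = 0

    def __post_init__(self):
        if len(self.wt_sequence) != len(self.mut_sequence):
            raise ValidationError(f"{self.pair_id}: sequences differ in length")
        diffs = [i for i, (a, b) in enumerate(zip(self.wt_sequence,
                                                  self.mut_sequence)) if a != b]
        if len(diffs) != 1:
            raise ValidationError(
                f"{self.pair_id}: sequences must differ at exactly one residue "
                f"(found {len(diffs)})")
        expected = self.core_start + self.core_position - 1
        if diffs[0] != expected:
            raise ValidationError(
                f"{self.pair_id}: substitution at offset {diffs[0]}, but "
                f"core_position {self.core_position} implies offset {expected}")
        if not 1 <= self.core_position <= CORE_LENGTH:
            raise ValidationError(f"{self.pair_id}: core position outside 1..9")
        if self.activity_wt <= 0 or self.activity_mut <= 0:
            raise ValidationError(f"{self.pair_id}: activities must be positive")

    @property
    def wt_aa(self) -> str:
        return self.wt_sequence[self.core_start + self.core_position - 1]

    @property
    def mut_aa(self) -> str:
        return self.mut_sequence[self.core_start + self.core_position - 1]

    def swapped(self) -> "MutationPair":
        return MutationPair(self.pair_id, self.mut_sequence, self.wt_sequence,
                            self.core_position, self.activity_mut,
                            self.activity_wt, self.core_start)


def experimental_sign(pair: MutationPair) -> int:
    """Sign of the experimental activity difference (mut - wt)."""
    return int(np.sign(pair.activity_mut - pair.activity_wt))


def matrix_sign(matrix: StructMatrix, pair: MutationPair) -> int:
    """Predicted sign from the scoring matrix: sign(E[mut] - E[wt])."""
    if pair.wt_aa == pair.mut_aa:
        return 0
    delta = (matrix.energy(pair.core_position, pair.mut_aa)
             - matrix.energy(pair.core_position, pair.wt_aa))
    return int(np.sign(delta))


# ---------------------------------------------------------------------------
# Consensus over external scoring functions
# ---------------------------------------------------------------------------

def function_signs(scores: pd.DataFrame,
                   orientations: Mapping[str, str] | None = None) -> dict[str, int]:
    """Per-function predicted sign for one pair's score table.

    ``scores`` holds columns role ('wt'/'mut'), function, frame, score.
    Orientation 'asc' (default) means lower score = better binder, so a
    positive mean difference (mut - wt) predicts weakened binding (+1);
    'desc' flips the sign.
    """
    orientations = dict(orientations or {})
    out: dict[str, int] = {}
    for fn, sub in scores.groupby("function", sort=False):
        roles = set(sub["role"])
        if roles != {"wt", "mut"}:
            raise ValidationError(f"function '{fn}': need both wt and mut scores")
        mean_wt = sub.loc[sub["role"] == "wt", "score"].mean()
        mean_mut = sub.loc[sub["role"] == "mut", "score"].mean()
        sign = int(np.sign(mean_mut - mean_wt))
        if orientations.get(fn, "asc") == "desc":
            sign = -sign
        out[fn] = sign
    return out


def consensus_sign(scores: pd.DataFrame, exp_sign: int, min_agree: int = 3,
                   orientations: Mapping[str, str] | None = None) -> bool:
    """True when >= ``min_agree`` functions' signs equal the experimental sign."""
    if exp_sign == 0:
        return False
    signs = function_signs(scores, orientations)
    return sum(1 for s in signs.values() if s == exp_sign) >= min_agree


def consensus_matches(score_table: pd.DataFrame, pairs: Sequence[MutationPair],
                      min_agree: int = 3,
                      orientations: Mapping[str, str] | None = None) -> np.ndarray:
    """Per-pair consensus match indicators for a multi-pair score table."""
    grouped = dict(tuple(score_table.groupby("pair_id", sort=False)))
    out = np.zeros(len(pairs), dtype=bool)
    for i, pair in enumerate(pairs):
        sub = grouped.get(pair.pair_id)
        if sub is None:
            raise ValidationError(f"no scores for pair '{pair.pair_id}'")
        out[i] = consensus_sign(sub, experimental_sign(pair), min_agree,
                                orientations)
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def combine_or(matches_a: np.ndarray, matches_b: np.ndarray) -> np.ndarray:
    """Conditional-'or' combination of two methods' per-pair matches."""
    a = np.asarray(matches_a, dtype=bool)
    b = np.asarray(matches_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"pair sets differ in size: {a.shape} vs {b.shape}")
    return a | b


@dataclass(frozen=True)
class EvaluationResult:
    n_pairs: int
    n_matched: int
    match_fraction: float
    bootstrap_mean: float | None = None
    bootstrap_sd: float | None = None
    n_replicas: int | None = None
    seed: int | None = None


def evaluate(matches: np.ndarray) -> EvaluationResult:
    """Point estimate of the match fraction (3-decimal report convention)."""
    m = np.asarray(matches, dtype=bool)
    if m.size == 0:
        raise ParameterError("cannot evaluate an empty match vector")
    return EvaluationResult(n_pairs=int(m.size), n_matched=int(m.sum()),
                            match_fraction=round(float(m.mean()), 3))


def bootstrap(matches: np.ndarray, n_replicas: int = 50,
              seed: int = 0) -> tuple[float, float]:
    """Bootstrap mean and SD of the match fraction over resampled pairs.

    Each replica draws n pairs with replacement; SD is the sample standard
    deviation (ddof=1) over replicate fractions.  Deterministic under seed.
    """
    m = np.asarray(matches, dtype=bool)
    if m.size < 2:
        raise ParameterError("bootstrap needs >= 2 pairs")
    if n_replicas < 2:
        raise ParameterError("bootstrap needs >= 2 replicas")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m.size, size=(n_replicas, m.size))
    fractions = m[idx].mean(axis=1)
    return float(fractions.mean()), float(fractions.std(ddof=1))


def evaluate_with_bootstrap(matches: np.ndarray, n_replicas: int = 50,
                            seed: int = 0) -> EvaluationResult:
    point = evaluate(matches)
    mean, sd = bootstrap(matches, n_replicas=n_replicas, seed=seed)
    return EvaluationResult(n_pairs=point.n_pairs, n_matched=point.n_matched,
                            match_fraction=point.match_fraction,
                            bootstrap_mean=mean, bootstrap_sd=sd,
                            n_replicas=n_replicas, seed=seed)


def matrix_matches(matrix: StructMatrix, pairs: Sequence[MutationPair],
                   exclude_experimental_ties: bool = True
                   ) -> tuple[np.ndarray, list[MutationPair]]:
    """Per-pair match indicators of matrix_sign against experimental_sign.

    Pairs with experimental sign 0 are excluded from the denominator by
    default (they carry no usable sign); predicted ties count as non-matches.
    """
    kept: list[MutationPair] = []
    matches: list[bool] = []
    for pair in pairs:
        es = experimental_sign(pair)
        if es == 0 and exclude_experimental_ties:
            continue
        kept.append(pair)
        matches.append(matrix_sign(matrix, pair) == es)
    return np.array(matches, dtype=bool), kept


# ---------------------------------------------------------------------------
# Pair assembly
# ---------------------------------------------------------------------------

def make_pairs(peptides: pd.DataFrame) -> list[MutationPair]:
    """All unordered single-substitution pairs in a peptide dataset.

    ``peptides`` needs columns sequence, activity_nM and optionally
    core_start (default 0).  A pair requires the full sequences to differ at
    exactly one residue, located inside the 9-mer core; the stronger binder
    (lower nM) is taken as wild type.
    """
    if "core_start" not in peptides.columns:
        peptides = peptides.assign(core_start=0)
    rows = list(peptides.itertuples(index=False))
    # bucket by (length, core_start, masked sequence): Hamming-1 neighbours
    # share exactly one mask
    buckets: dict[tuple[int, int, str], list[int]] = {}
    for i, r in enumerate(rows):
        seq = r.sequence
        for p in range(len(seq)):
            key = (len(seq), int(r.core_start), seq[:p] + "*" + seq[p + 1:])
            buckets.setdefault(key, []).append(i)
    pairs: list[MutationPair] = []
    for (length, core_start, mask), members in buckets.items():
        if len(members) < 2:
            continue
        p = mask.index("*")
        core_pos = p - core_start + 1
        if not 1 <= core_pos <= CORE_LENGTH:
            continue
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                a, b = rows[members[ai]], rows[members[bi]]
                if a.sequence[p] == b.sequence[p]:
                    continue  # identical sequences: not a substitution
                wt, mut = ((a, b) if a.activity_nM <= b.activity_nM else (b, a))
                pairs.append(MutationPair(
                    pair_id=f"{wt.sequence}_{mut.sequence}",
                    wt_sequence=wt.sequence, mut_sequence=mut.sequence,
                    core_position=core_pos,
                    activity_wt=float(wt.activity_nM),
                    activity_mut=float(mut.activity_nM),
                    core_start=core_start))
    pairs.sort(key=lambda pr: pr.pair_id)
    return pairs


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_pairs(pairs: Sequence[MutationPair], path: str | Path) -> None:
    df = pd.DataFrame([{
        "pair_id": p.pair_id, "wt_sequence": p.wt_sequence,
        "mut_sequence": p.mut_sequence, "core_position": p.core_position,
        "activity_wt": p.activity_wt, "activity_mut": p.activity_mut,
        "core_start": p.core_start,
    } for p in pairs])
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[MutationPair]:
    df = pd.read_csv(path, sep="\t")
    if "core_start" not in df.columns:
        df = df.assign(core_start=0)
    return [MutationPair(pair_id=str(r.pair_id), wt_sequence=r.wt_sequence,
                         mut_sequence=r.mut_sequence,
                         core_position=int(r.core_position),
                         activity_wt=float(r.activity_wt),
                         activity_mut=float(r.activity_mut),
                         core_start=int(r.core_start))
            for r in df.itertuples(index=False)]


def write_score_table(df: pd.DataFrame, orientations: Mapping[str, str],
                      path: str | Path) -> None:
    """Score-table TSV with ``#orientation fn=asc|desc`` header comments."""
    lines = [f"#orientation {fn}={orient}" for fn, orient in orientations.items()]
    body = df[SCORE_TABLE_COLUMNS].to_csv(sep="\t", index=False)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_score_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    orientations: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#orientation"):
            _, spec = line.split(None, 1)
            fn, orient = spec.split("=")
            if orient not in ("asc", "desc"):
                raise ValidationError(f"{path}: orientation must be asc|desc")
            orientations[fn.strip()] = orient
            data_start = i + 1
        elif not line.startswith("#"):
            break
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[data_start:])), sep="\t")
    return df, orientations


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    predictions[["method", "pair_id", "sign"]].to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
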