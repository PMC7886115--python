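"""Trial schedules, movement-time calibration, and item-to-position yoking.

Stimuli live on a 3x3 grid of nine touch positions (indices 0-8, row-major).
Three schedule-building stages mirror the experimental protocol:

1. a *training* phase of random position triplets that measures movement time
   between every ordered pair of grid positions,
2. *yoking*: an exhaustive search over all injective assignments of the design
   items to grid positions, choosing the one whose eight design transitions
   have movement times as close as possible,
3. the blocked *learning* phase (by default 10 blocks of 40 trials, with
   per-block triplet counts apportioned by largest remainder from the design
   frequencies) followed by a *switch* phase built from the switched design.

All randomisation is driven by a single seed (or an externally supplied
:class:`numpy.random.Generator`), and identical seeds yield identical
schedules.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence as SequenceT

import numpy as np
import pandas as pd

from .design import DesignSpec, Seq, build_switch, enumerate_transitions, seq_label

__all__ = [
    "N_POSITIONS",
    "grid_coords",
    "grid_distance",
    "TransitionTimeMatrix",
    "ItemMapping",
    "ScheduledTrial",
    "Schedule",
    "ScheduleInfeasibleError",
    "IncompleteMatrixError",
    "build_training_schedule",
    "estimate_transition_times",
    "yoke_items",
    "largest_remainder",
    "build_experiment_schedule",
]

N_POSITIONS = 9


class ScheduleInfeasibleError(ValueError):
    """The requested schedule cannot satisfy its coverage constraints."""


class IncompleteMatrixError(ValueError):
    """A transition-time matrix has unobserved ordered pairs."""


def grid_coords(index: int) -> tuple[int, int]:
    """(row, col) of a grid position index, row-major on the 3x3 grid."""
    if not 0 <= index < N_POSITIONS:
        raise ValueError(f"grid index {index} out of range 0-{N_POSITIONS - 1}")
    return divmod(index, 3)


def grid_distance(a: int, b: int) -> float:
    """Euclidean distance between two grid positions on unit-spaced coordinates."""
    (ra, ca), (rb, cb) = grid_coords(a), grid_coords(b)
    return math.hypot(ra - rb, ca - cb)


@dataclass
class TransitionTimeMatrix:
    """Mean movement times (ms) between ordered grid-position pairs.

    ``times`` is a 9x9 array; the diagonal is undefined (NaN) and unobserved
    pairs are NaN as well.  ``counts`` records how many observations entered
    each mean.
    """

    times: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (N_POSITIONS, N_POSITIONS):
            raise ValueError("transition-time matrix must be 9x9")
        if self.counts is None:
            self.counts = np.where(np.isfinite(self.times), 1, 0)
        off = ~np.eye(N_POSITIONS, dtype=bool)
        defined = self.times[off]
        defined = defined[np.isfinite(defined)]
        if np.any(defined <= 0):
            raise ValueError("defined transition times must be positive")

    @property
    def missing_pairs(self) -> list[tuple[int, int]]:
        out = []
        for i in range(N_POSITIONS):
            for j in range(N_POSITIONS):
                if i != j and not np.isfinite(self.times[i, j]):
                    out.append((i, j))
        return out

    @property
    def is_complete(self) -> bool:
        return not self.missing_pairs


@dataclass(frozen=True)
class ItemMapping:
    """Injective assignment of design items to grid positions."""

    items: tuple[str, ...]
    positions: tuple[int, ...]
    objective: str = "range"
    objective_value: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.items) != len(self.positions):
            raise ValueError("items and positions must have equal length")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("mapping must be injective")
        if any(not 0 <= p < N_POSITIONS for p in self.positions):
            raise ValueError("positions must lie on the 3x3 grid")

    def __getitem__(self, item: str) -> int:
        try:
            return self.positions[self.items.index(item)]
        except ValueError as exc:
            raise KeyError(f"mapping has no position for item {item!r}") from exc

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.items, self.positions))


class ScheduledTrial(NamedTuple):
    phase: str
    block: int
    trial: int
    sequence: tuple


@dataclass
class Schedule:
    """An ordered list of trials with the seed that generated it."""

    trials: list[ScheduledTrial]
    seed: object = None
    design: DesignSpec | None = None
    switch_design: DesignSpec | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phase": t.phase,
                "block": t.block,
                "trial": t.trial,
                "item1": t.sequence[0],
                "item2": t.sequence[1],
                "item3": t.sequence[2],
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# training phase
# ---------------------------------------------------------------------------


def build_training_schedule(
    n_trials: int = 224,
    n_positions: int = N_POSITIONS,
    seed=None,
    balanced: bool = True,
    min_count: int | None = None,
    max_attempts: int = 50,
) -> Schedule:
    """Random position triplets covering every ordered position pair.

    Each trial is a triplet of three pairwise-distinct grid positions and
    contributes two adjacent transitions.  In balanced mode (default) a greedy
    max-deficit chaining guarantees every one of the ``n*(n-1)`` ordered pairs
    occurs at least ``floor(2*n_trials / n_pairs)`` times (6 for the default
    224 trials on 9 positions), the remainder being random; in unbalanced mode
    triplets are fully random.

    Raises :class:`ScheduleInfeasibleError` when the requested minimum
    coverage exceeds the ``2*n_trials`` available transitions.
    """
    pairs = [(i, j) for i in range(n_positions) for j in range(n_positions) if i != j]
    n_pairs = len(pairs)
    if min_count is None:
        target = (2 * n_trials) // n_pairs if balanced else 0
    else:
        target = int(min_count)
    if target * n_pairs > 2 * n_trials:
        raise ScheduleInfeasibleError(
            f"cannot place {target} copies of {n_pairs} ordered pairs "
            f"in {2 * n_trials} transitions"
        )
    master = np.random.default_rng(seed)
    if not balanced:
        trials = []
        for t in range(n_trials):
            trio = tuple(int(p) for p in master.choice(n_positions, size=3, replace=False))
            trials.append(ScheduledTrial("training", 1, t + 1, trio))
        return Schedule(trials, seed=seed)

    for _attempt in range(max_attempts):
        rng = np.random.default_rng(master.integers(2**31))
        counts = np.zeros((n_positions, n_positions), dtype=int)
        trials: list[ScheduledTrial] = []
        for t in range(n_trials):
            deficit = target - counts
            np.fill_diagonal(deficit, -(10**9))
            best = deficit.max()
            cand = np.argwhere(deficit == best)
            p1, p2 = cand[rng.integers(len(cand))]
            row = deficit[p2].copy()
            row[[p1, p2]] = -(10**9)
            cand3 = np.flatnonzero(row == row.max())
            p3 = int(cand3[rng.integers(len(cand3))])
            counts[p1, p2] += 1
            counts[p2, p3] += 1
            trials.append(ScheduledTrial("training", 1, t + 1, (int(p1), int(p2), p3)))
        off = ~np.eye(n_positions, dtype=bool)
        if counts[off].min() >= target:
            return Schedule(trials, seed=seed)
    raise ScheduleInfeasibleError(
        f"could not reach coverage {target} per ordered pair in {max_attempts} attempts"
    )


def estimate_transition_times(records: pd.DataFrame) -> TransitionTimeMatrix:
    """Mean movement time per ordered position pair from training records.

    ``records`` must carry ``pos1, pos2, pos3, tt1, tt2`` columns (one row per
    training trial); each trial contributes the pair ``pos1->pos2`` with time
    ``tt1`` and ``pos2->pos3`` with ``tt2``.  Unobserved pairs are left NaN
    and flagged via :attr:`TransitionTimeMatrix.missing_pairs`.
    """
    sums = np.zeros((N_POSITIONS, N_POSITIONS))
    counts = np.zeros((N_POSITIONS, N_POSITIONS), dtype=int)
    for frm, to, rt in (("pos1", "pos2", "tt1"), ("pos2", "pos3", "tt2")):
        i = records[frm].to_numpy(dtype=int)
        j = records[to].to_numpy(dtype=int)
        v = records[rt].to_numpy(dtype=float)
        np.add.at(sums, (i, j), v)
        np.add.at(counts, (i, j), 1)
    with np.errstate(invalid="ignore"):
        times = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(times, np.nan)
    return TransitionTimeMatrix(times, counts)


# ---------------------------------------------------------------------------
# yoking
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=4)
def _permutation_array(n: int, k: int) -> np.ndarray:
    """All injective assignments of k items into n positions, in lexicographic order."""
    return np.array(list(itertools.permutations(range(n), k)), dtype=np.intp)


def yoke_items(
    tt: TransitionTimeMatrix | np.ndarray,
    design: DesignSpec,
    objective: str = "range",
) -> ItemMapping:
    """Exhaustively choose the item-to-position mapping equalising transition times.

    Over all injective mappings of the design items into the nine grid
    positions (60480 candidates for six items), returns the one minimising the
    chosen objective over the design's transition times: ``"range"``
    (max - min, the default) or ``"variance"``.  Ties break to the
    lexicographically first mapping (items in sorted order, positions compared
    left to right).
    """
    if objective not in ("range", "variance"):
        raise ValueError(f"objective must be 'range' or 'variance', got {objective!r}")
    times = tt.times if isinstance(tt, TransitionTimeMatrix) else np.asarray(tt, float)
    if isinstance(tt, TransitionTimeMatrix) and not tt.is_complete:
        raise IncompleteMatrixError(
            f"transition-time matrix is missing pairs: {tt.missing_pairs}"
        )
    items = design.alphabet
    index = {item: i for i, item in enumerate(items)}
    transitions = sorted(enumerate_transitions(design))
    ifrom = np.array([index[a] for _, a, _ in transitions])
    ito = np.array([index[b] for _, _, b in transitions])
    perms = _permutation_array(N_POSITIONS, len(items))
    vals = times[perms[:, ifrom], perms[:, ito]]  # (n_perms, n_transitions)
    if not np.all(np.isfinite(vals)):
        raise IncompleteMatrixError("a required transition time is undefined")
    if objective == "range":
        obj = vals.max(axis=1) - vals.min(axis=1)
    else:
        obj = vals.var(axis=1)
    best = int(np.argmin(obj))  # first occurrence = lexicographically first
    return ItemMapping(
        items, tuple(int(p) for p in perms[best]), objective, float(obj[best])
    )


# ---------------------------------------------------------------------------
# learning + switch phases
# ---------------------------------------------------------------------------


def largest_remainder(frequencies: SequenceT[float], total: int) -> list[int]:
    """Integer apportionment of ``total`` proportional to ``frequencies``.

    Floors each quota and hands the remaining units to the largest fractional
    parts, ties broken by list order.  Each count differs from its exact quota
    by less than 1 and the counts sum to ``total``.
    """
    quotas = [f * total for f in frequencies]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = total - sum(counts)
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def build_experiment_schedule(
    design: DesignSpec,
    n_blocks: int = 10,
    block_size: int = 40,
    switch_blocks: int = 1,
    seed=None,
) -> Schedule:
    """Blocked learning-phase schedule followed by the switch phase.

    Every learning block contains ``largest_remainder(frequencies, block_size)``
    copies of each triplet — (16, 10, 10, 4) for the canonical design at block
    size 40 — uniformly shuffled within the block.  Switch blocks are built
    from :func:`~xorseq.design.build_switch` with the same allocation rule and
    numbered after the learning blocks.
    """
    rng = np.random.default_rng(seed)
    counts = largest_remainder(design.frequencies, block_size)
    if any(c == 0 for c in counts):
        warnings.warn(
            "some sequences receive zero occurrences per block at this block size",
            stacklevel=2,
        )
    switch_design = build_switch(design) if switch_blocks > 0 else None

    trials: list[ScheduledTrial] = []
    trial_no = 0

    def add_blocks(phase: str, spec: DesignSpec, first_block: int, n: int) -> None:
        nonlocal trial_no
        for b in range(first_block, first_block + n):
            pool = [s for s, c in zip(spec.sequences, counts) for _ in range(c)]
            order = rng.permutation(len(pool))
            for k in order:
                trial_no += 1
                trials.append(ScheduledTrial(phase, b, trial_no, pool[int(k)]))

    add_blocks("learning", design, 1, n_blocks)
    if switch_blocks > 0:
        add_blocks("switch", switch_design, n_blocks + 1, switch_blocks)
    return Schedule(trials, seed=seed, design=design, switch_design=switch_design)
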