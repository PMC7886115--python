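"""Synthetic participants for the XOR sequence-learning task.

No mechanistic reaction-time model is claimed for the real task; the generator
here is the simplest process that reproduces the qualitative structure the
analysis pipeline is built to detect.  A simulated participant incrementally
tracks first- and second-order transitional probabilities with a
pseudocount-smoothed count estimator and responds faster the more predictable
the upcoming stimulus is:

``TT1 = baseline + motor_cost * d(pos1, pos2) - gain1 * p̂(2nd|1st) + noise``

``TT2 = baseline + motor_cost * d(pos2, pos3) - gain1 * p̂(3rd|2nd)
        - gain2 * p̂(3rd|1st,2nd) * [p̂(3rd|2nd) >= w2_threshold] + noise``

The indicator gate reflects the finding that second-order knowledge is only
deployed when the supporting first-order transition is strong enough; with the
default threshold the lowest-TP sequence never engages its (perfect)
second-order predictor.  Unseen contexts contribute predictability 0 so the
first trial is well defined, and response times are floored at a positive
minimum.

:func:`simulate_cohort` runs the full per-participant protocol — training,
movement-time estimation, yoking, blocked learning and switch — and returns a
tidy trial table shaped like the deidentified data the experiment produces.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .design import DesignSpec, Seq, seq_label
from .scheduler import (
    ItemMapping,
    Schedule,
    build_experiment_schedule,
    build_training_schedule,
    estimate_transition_times,
    grid_distance,
    yoke_items,
)

__all__ = [
    "LearnerParams",
    "TransitionEstimator",
    "update_estimates",
    "simulate_training",
    "simulate_participant",
    "simulate_cohort",
]


@dataclass(frozen=True)
class LearnerParams:
    """Parameters of the synthetic participant.

    Attributes
    ----------
    baseline_rt : float
        Mean response time (ms) with zero predictability and zero distance.
    baseline_sd : float
        Between-participant SD (ms) of the baseline, applied by
        :func:`simulate_cohort`.
    motor_cost : float
        ms per unit grid distance travelled.
    gain1, gain2 : float
        RT reduction (ms) per unit of first-/second-order predictability.
    freq_gain : float
        RT reduction (ms) per unit of running sequence-frequency estimate;
        0 by default — used to generate frequency-driven (rather than
        TP-driven) data for model-recovery checks.
    w2_threshold : float
        Minimum running first-order TP for second-order knowledge to be
        deployed; set to 0 to disable the gate.
    smoothing : float
        Pseudocount of the TP estimators.  Larger values slow apparent
        learning so that predictability keeps growing across all blocks.
    noise_sd : float
        Additive Gaussian trial noise (ms).
    lognorm_sigma : float
        Optional multiplicative lognormal noise (0 disables).
    rt_floor : float
        Hard lower bound (ms) on emitted response times.
    """

    baseline_rt: float = 500.0
    baseline_sd: float = 40.0
    motor_cost: float = 30.0
    gain1: float = 300.0
    gain2: float = 120.0
    freq_gain: float = 0.0
    w2_threshold: float = 0.3
    smoothing: float = 2.0
    noise_sd: float = 35.0
    lognorm_sigma: float = 0.0
    rt_floor: float = 50.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_rt <= 0:
            raise ValueError("baseline_rt must be positive")
        if min(self.gain1, self.gain2, self.freq_gain, self.noise_sd) < 0:
            raise ValueError("gains and noise_sd must be nonnegative")
        if not 0.0 <= self.w2_threshold <= 1.0:
            raise ValueError("w2_threshold must lie in [0, 1]")
        if self.smoothing < 0:
            raise ValueError("smoothing must be nonnegative")


class TransitionEstimator:
    """Incremental pseudocount estimator of transitional probabilities.

    Maintains positional pair counts, prefix-triplet counts and sequence
    counts.  Estimates are ``(count + s) / (context_count + s * K)`` with
    pseudocount ``s`` and ``K`` possible successors (the alphabet size); an
    unseen context with ``s = 0`` yields probability 0 rather than an error,
    because a predicting learner simply has nothing to predict from yet.
    """

    def __init__(self, alphabet: Iterable[str], smoothing: float = 0.0) -> None:
        self.alphabet = tuple(sorted(set(alphabet)))
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        self.k = len(self.alphabet)
        self.smoothing = float(smoothing)
        self.pair_counts: dict[tuple[int, int], Counter] = {(1, 2): Counter(), (2, 3): Counter()}
        self.ctx_counts: dict[tuple[int, int], Counter] = {(1, 2): Counter(), (2, 3): Counter()}
        self.triplet_counts: Counter = Counter()
        self.prefix_counts: Counter = Counter()
        self.seq_counts: Counter = Counter()
        self.n_sequences = 0

    def update(self, sequence: Seq) -> "TransitionEstimator":
        s = tuple(sequence)
        for i in range(min(len(s), 3) - 1):
            pos = (i + 1, i + 2)
            self.pair_counts[pos][(s[i], s[i + 1])] += 1
            self.ctx_counts[pos][s[i]] += 1
        if len(s) >= 2:
            self.prefix_counts[(s[0], s[1])] += 1
        if len(s) >= 3:
            self.triplet_counts[(s[0], s[1], s[2])] += 1
        self.seq_counts[s] += 1
        self.n_sequences += 1
        return self

    def _smooth(self, count: int, ctx: int) -> float:
        s = self.smoothing
        den = ctx + s * self.k
        if den <= 0:
            return 0.0
        return (count + s) / den

    def p_first(self, from_item: str, to_item: str, positions: tuple[int, int]) -> float:
        return self._smooth(
            self.pair_counts[positions][(from_item, to_item)],
            self.ctx_counts[positions][from_item],
        )

    def p_second(self, first: str, second: str, third: str) -> float:
        return self._smooth(
            self.triplet_counts[(first, second, third)],
            self.prefix_counts[(first, second)],
        )

    def p_seq(self, sequence: Seq) -> float:
        if self.n_sequences == 0:
            return 0.0
        return self.seq_counts[tuple(sequence)] / self.n_sequences


def update_estimates(state: TransitionEstimator, observed: Seq) -> TransitionEstimator:
    """Feed one observed sequence into the estimator state (in place)."""
    return state.update(observed)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _noise(rng: np.random.Generator, params: LearnerParams) -> float:
    return float(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 0.0


def _finalise(rt: float, rng: np.random.Generator, params: LearnerParams) -> float:
    if params.lognorm_sigma > 0:
        rt *= float(np.exp(rng.normal(0.0, params.lognorm_sigma)))
    return max(rt, params.rt_floor)


def simulate_training(
    schedule: Schedule, params: LearnerParams, rng=None
) -> pd.DataFrame:
    """Response times for a training schedule of random position triplets.

    No sequence structure exists to learn, so
    ``RT = baseline + motor_cost * distance + noise``.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    rows = []
    for t in schedule.trials:
        p1, p2, p3 = t.sequence
        tt1 = _finalise(
            params.baseline_rt + params.motor_cost * grid_distance(p1, p2) + _noise(rng, params),
            rng,
            params,
        )
        tt2 = _finalise(
            params.baseline_rt + params.motor_cost * grid_distance(p2, p3) + _noise(rng, params),
            rng,
            params,
        )
        rows.append(
            {
                "phase": t.phase,
                "block": t.block,
                "trial": t.trial,
                "pos1": p1,
                "pos2": p2,
                "pos3": p3,
                "tt1": tt1,
                "tt2": tt2,
            }
        )
    return pd.DataFrame(rows)


def simulate_participant(
    schedule: Schedule,
    mapping: ItemMapping,
    params: LearnerParams,
    rng=None,
    participant_id: str = "P01",
    estimator: TransitionEstimator | None = None,
) -> pd.DataFrame:
    """Simulate one participant over an experiment schedule.

    Running probability estimates are recorded *before* each trial's update,
    so the table reflects the knowledge the participant acted on.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    alphabet = (
        schedule.design.alphabet
        if schedule.design is not None
        else tuple(sorted({i for t in schedule.trials for i in t.sequence}))
    )
    est = estimator if estimator is not None else TransitionEstimator(alphabet, params.smoothing)
    positions = {}
    for item in alphabet:
        try:
            positions[item] = mapping[item]
        except KeyError as exc:
            raise ValueError(f"item mapping is missing design item {item!r}") from exc
    rows = []
    for t in schedule.trials:
        x, y, z = t.sequence
        p1 = est.p_first(x, y, (1, 2))
        p2_first = est.p_first(y, z, (2, 3))
        p2_second = est.p_second(x, y, z)
        p_freq = est.p_seq(t.sequence)
        gate = 1.0 if p2_first >= params.w2_threshold else 0.0
        tt1 = (
            params.baseline_rt
            + params.motor_cost * grid_distance(positions[x], positions[y])
            - params.gain1 * p1
            - params.freq_gain * p_freq
            + _noise(rng, params)
        )
        tt2 = (
            params.baseline_rt
            + params.motor_cost * grid_distance(positions[y], positions[z])
            - params.gain1 * p2_first
            - params.gain2 * p2_second * gate
            - params.freq_gain * p_freq
            + _noise(rng, params)
        )
        rows.append(
            {
                "participant": participant_id,
                "phase": t.phase,
                "block": t.block,
                "trial": t.trial,
                "seq": seq_label(t.sequence),
                "item1": x,
                "item2": y,
                "item3": z,
                "pos1": positions[x],
                "pos2": positions[y],
                "pos3": positions[z],
                "tt1": _finalise(tt1, rng, params),
                "tt2": _finalise(tt2, rng, params),
                "phat1": p1,
                "phat2_first": p2_first,
                "phat2_second": p2_second,
            }
        )
        est.update(t.sequence)
    return pd.DataFrame(rows)


def simulate_cohort(
    design: DesignSpec,
    n_participants: int = 38,
    params: LearnerParams | None = None,
    master_seed=None,
    *,
    n_blocks: int = 10,
    block_size: int = 40,
    switch_blocks: int = 1,
    n_training: int = 224,
    objective: str = "range",
) -> pd.DataFrame:
    """Simulate a full cohort: training, yoking, learning and switch per participant.

    Per-participant random streams are spawned from ``master_seed``, so a
    fixed master seed reproduces the cohort table exactly while participants
    remain mutually independent.  Each participant receives an independent
    baseline drawn from ``N(baseline_rt, baseline_sd)`` (truncated at twice
    the RT floor), an independent training schedule, the yoked item mapping
    derived from their own simulated movement times, and an independent trial
    order.
    """
    params = params or LearnerParams()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_participants)
    width = max(2, len(str(n_participants)))
    tables = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        baseline = params.baseline_rt + params.baseline_sd * float(rng.normal())
        baseline = max(baseline, 2 * params.rt_floor)
        p_i = replace(params, baseline_rt=baseline)
        training = build_training_schedule(n_training, seed=rng)
        train_records = simulate_training(training, p_i, rng)
        ttm = estimate_transition_times(train_records)
        mapping = yoke_items(ttm, design, objective)
        schedule = build_experiment_schedule(
            design, n_blocks=n_blocks, block_size=block_size,
            switch_blocks=switch_blocks, seed=rng,
        )
        table = simulate_participant(
            schedule, mapping, p_i, rng, participant_id=f"P{i + 1:0{width}d}"
        )
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
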