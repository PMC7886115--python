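"""Weighted sequence inventories and the transitional-probability calculus.

A :class:`DesignSpec` is a weighted inventory of short item sequences (pairs or
triplets) with relative presentation frequencies.  From it one can compute

* first-order transitional probabilities ``p(Y|X)`` — the probability that item
  ``Y`` immediately follows item ``X``, either at a specific within-sequence
  position pair (``(1, 2)`` or ``(2, 3)``) or position-agnostically,
* second-order transitional probabilities ``p(Z|X, Y)`` — the probability of
  the third item given the ordered pair of the first two,
* non-adjacent transitional probabilities ``p(Z|X)`` from the first to the
  third item.

The module also validates the exclusive-or (XOR) structure used in sequence
learning experiments — four triplets in which the third item is perfectly
determined by the *combination* of the first two (``p(Z|X,Y) = 1``) but by
neither alone — and constructs the matching switch-phase design, in which the
third items are permuted across triplets so that every adjacent item pair is
preserved while every learned triplet combination becomes invalid.

Frequency and first-order TP dissociate in unbalanced designs: a pair can be
the most frequent without carrying the highest transitional probability, which
is exactly the manipulation these designs exist for.

Probabilities are kept at full float precision internally; rounding to the
conventional two decimals is presentation-only (see :func:`tp_table`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence as SequenceT, Union

import pandas as pd
import yaml

__all__ = [
    "Item",
    "Seq",
    "Positions",
    "DesignSpec",
    "TransitionStats",
    "XorReport",
    "UndefinedContextError",
    "NoValidSwitchError",
    "first_order_tp",
    "second_order_tp",
    "nonadjacent_tp",
    "transition_stats",
    "validate_xor",
    "build_switch",
    "enumerate_transitions",
    "switch_tp_report",
    "tp_table",
]

Item = str
Seq = tuple[Item, ...]
#: either an adjacent within-sequence position pair (1-based), or "any" for the
#: position-agnostic mode used in the worked restaurant examples.
Positions = Union[tuple[int, int], Literal["any"]]

_TOL = 1e-9


class UndefinedContextError(ValueError):
    """The conditioning context never occurs in the design.

    Raised instead of returning 0 or NaN so that downstream prediction code can
    distinguish "never seen" from "seen but never followed by this successor".
    """


class NoValidSwitchError(ValueError):
    """No permutation of third items yields a valid switch design."""


def _as_seq(seq: Iterable[Item] | str) -> Seq:
    if isinstance(seq, str):
        return tuple(seq)
    return tuple(seq)


def seq_label(seq: Seq) -> str:
    """Human-readable label: ``"ABC"`` for single-character items, else dashed."""
    if all(len(item) == 1 for item in seq):
        return "".join(seq)
    return "-".join(seq)


@dataclass(frozen=True)
class DesignSpec:
    """A weighted inventory of item sequences.

    Parameters
    ----------
    sequences
        Distinct sequences of 2 or 3 items; items within a sequence are
        pairwise distinct (stimulus positions never repeat within a trial).
    frequencies
        Relative presentation frequencies, each in ``(0, 1]``, summing to 1.
    """

    sequences: tuple[Seq, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        sequences = tuple(_as_seq(s) for s in self.sequences)
        frequencies = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "sequences", sequences)
        object.__setattr__(self, "frequencies", frequencies)
        if not sequences:
            raise ValueError("design must contain at least one sequence")
        if len(sequences) != len(frequencies):
            raise ValueError("sequences and frequencies must have equal length")
        if len(set(sequences)) != len(sequences):
            raise ValueError("sequences must be distinct")
        for s in sequences:
            if not 2 <= len(s) <= 3:
                raise ValueError(f"sequence {s!r} must have 2 or 3 items")
            if len(set(s)) != len(s):
                raise ValueError(f"items within a sequence must be distinct: {s!r}")
        for f in frequencies:
            if not 0.0 < f <= 1.0:
                raise ValueError(f"frequency {f} not in (0, 1]")
        if abs(sum(frequencies) - 1.0) > _TOL:
            raise ValueError(f"frequencies must sum to 1, got {sum(frequencies)}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_strings(
        cls, sequences: SequenceT[str], frequencies: SequenceT[float]
    ) -> "DesignSpec":
        """Build from compact labels, one character per item (e.g. ``"ABC"``)."""
        return cls(tuple(tuple(s) for s in sequences), tuple(frequencies))

    @classmethod
    def from_counts(
        cls, sequences: SequenceT[Iterable[Item] | str], counts: SequenceT[float]
    ) -> "DesignSpec":
        """Build from raw occurrence counts, normalising to proportions."""
        total = float(sum(counts))
        if total <= 0:
            raise ValueError("counts must sum to a positive number")
        return cls(
            tuple(_as_seq(s) for s in sequences),
            tuple(c / total for c in counts),
        )

    # -- basic views --------------------------------------------------------

    @property
    def alphabet(self) -> tuple[Item, ...]:
        """Sorted tuple of all distinct items in the design."""
        return tuple(sorted({item for s in self.sequences for item in s}))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(seq_label(s) for s in self.sequences)

    def frequency_of(self, seq: Iterable[Item] | str) -> float:
        key = _as_seq(seq)
        for s, f in zip(self.sequences, self.frequencies):
            if s == key:
                return f
        raise KeyError(f"sequence {key!r} not in design")

    def items(self) -> Iterable[tuple[Seq, float]]:
        return zip(self.sequences, self.frequencies)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {"sequences": list(self.labels), "frequencies": list(self.frequencies)}

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        seqs = d.get("sequences", d.get("triplets"))
        if seqs is None:
            raise ValueError("design mapping needs a 'sequences' (or 'triplets') key")
        parsed = []
        for s in seqs:
            if isinstance(s, str):
                parsed.append(tuple(s) if "-" not in s else tuple(s.split("-")))
            else:
                parsed.append(tuple(s))
        return cls(tuple(parsed), tuple(d["frequencies"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# transitional probabilities
# ---------------------------------------------------------------------------


def _check_positions(positions: Positions) -> tuple[int, int] | None:
    if positions == "any":
        return None
    try:
        i, j = positions  # type: ignore[misc]
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"positions must be (i, i+1) or 'any', got {positions!r}") from exc
    if j != i + 1 or i < 1:
        raise ValueError(f"positions must be an adjacent 1-based pair, got {positions!r}")
    return (i, j)


def first_order_tp(
    design: DesignSpec, from_item: Item, to_item: Item, positions: Positions
) -> float:
    """First-order transitional probability ``p(to_item | from_item)``.

    With ``positions=(1, 2)`` or ``(2, 3)`` the probability is positional:
    conditioning weight is the total frequency of sequences carrying
    ``from_item`` at the conditioning position.  With ``positions="any"`` every
    occurrence of ``from_item`` counts in the denominator — including
    sequence-final occurrences with no successor — which is the convention
    under which a mixture of two- and three-course menus gives
    ``p(Dessert|Dish) = .80`` when a dessert follows a dish four times out of
    five.
    """
    pos = _check_positions(positions)
    num = 0.0
    den = 0.0
    if pos is None:
        for s, f in design.items():
            den += f * sum(1 for item in s if item == from_item)
            num += f * sum(
                1
                for i in range(len(s) - 1)
                if s[i] == from_item and s[i + 1] == to_item
            )
    else:
        a, b = pos[0] - 1, pos[1] - 1
        for s, f in design.items():
            if len(s) > a and s[a] == from_item:
                den += f
                if len(s) > b and s[b] == to_item:
                    num += f
    if den <= 0.0:
        raise UndefinedContextError(
            f"item {from_item!r} never occurs as a conditioning context "
            f"at positions {positions!r}"
        )
    return num / den


def second_order_tp(
    design: DesignSpec, first: Item, second: Item, third: Item
) -> float:
    """Second-order transitional probability ``p(third | first, second)``.

    Sequences that begin with the pair ``(first, second)`` but stop there
    (two-item sequences) count in the denominator: after Salad-Dish, dessert is
    chosen only half the time if half of those menus end at the dish.
    """
    num = 0.0
    den = 0.0
    for s, f in design.items():
        if len(s) >= 2 and s[0] == first and s[1] == second:
            den += f
            if len(s) >= 3 and s[2] == third:
                num += f
    if den <= 0.0:
        raise UndefinedContextError(
            f"pair ({first!r}, {second!r}) never occurs at positions 1-2"
        )
    return num / den


def nonadjacent_tp(design: DesignSpec, first: Item, third: Item) -> float:
    """Non-adjacent transitional probability ``p(third | first)`` (positions 1->3)."""
    num = 0.0
    den = 0.0
    for s, f in design.items():
        if s[0] == first:
            den += f
            if len(s) >= 3 and s[2] == third:
                num += f
    if den <= 0.0:
        raise UndefinedContextError(f"item {first!r} never occurs at position 1")
    return num / den


@dataclass(frozen=True)
class TransitionStats:
    """All transition probabilities and pair frequencies of a design.

    ``first_order`` and ``pair_frequency`` are keyed by
    ``(positions, from_item, to_item)``, ``nonadjacent`` by
    ``(first, third)`` and ``second_order`` by ``(first, second, third)``.
    Only observed transitions appear; within each conditioning context the
    probabilities over observed successors sum to 1.
    """

    first_order: dict[tuple[tuple[int, int], Item, Item], float]
    nonadjacent: dict[tuple[Item, Item], float]
    second_order: dict[tuple[Item, Item, Item], float]
    pair_frequency: dict[tuple[tuple[int, int], Item, Item], float]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: kind, positions, context, successor, probability, frequency."""
        rows = []
        for (pos, a, b), p in sorted(self.first_order.items()):
            rows.append(
                {
                    "kind": "first_order",
                    "positions": f"{pos[0]}-{pos[1]}",
                    "context": a,
                    "successor": b,
                    "probability": p,
                    "frequency": self.pair_frequency[(pos, a, b)],
                }
            )
        for (a, c), p in sorted(self.nonadjacent.items()):
            rows.append(
                {
                    "kind": "nonadjacent",
                    "positions": "1-3",
                    "context": a,
                    "successor": c,
                    "probability": p,
                    "frequency": float("nan"),
                }
            )
        for (a, b, c), p in sorted(self.second_order.items()):
            rows.append(
                {
                    "kind": "second_order",
                    "positions": "1-2->3",
                    "context": f"{a},{b}",
                    "successor": c,
                    "probability": p,
                    "frequency": float("nan"),
                }
            )
        return pd.DataFrame(rows)


def enumerate_transitions(
    design: DesignSpec,
) -> frozenset[tuple[tuple[int, int], Item, Item]]:
    """All distinct adjacent ordered transitions ``(positions, from, to)``."""
    out = set()
    for s, _ in design.items():
        for i in range(len(s) - 1):
            out.add(((i + 1, i + 2), s[i], s[i + 1]))
    return frozenset(out)


def transition_stats(design: DesignSpec) -> TransitionStats:
    """Compute every defined transition probability of the design."""
    first_order: dict = {}
    pair_frequency: dict = {}
    for pos, a, b in enumerate_transitions(design):
        first_order[(pos, a, b)] = first_order_tp(design, a, b, pos)
        i, j = pos[0] - 1, pos[1] - 1
        pair_frequency[(pos, a, b)] = sum(
            f
            for s, f in design.items()
            if len(s) > j and s[i] == a and s[j] == b
        )
    nonadj: dict = {}
    second: dict = {}
    for s, _ in design.items():
        if len(s) >= 3:
            nonadj[(s[0], s[2])] = nonadjacent_tp(design, s[0], s[2])
            second[(s[0], s[1], s[2])] = second_order_tp(design, *s[:3])
    return TransitionStats(first_order, nonadj, second, pair_frequency)


# ---------------------------------------------------------------------------
# XOR validation and the switch design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class XorReport:
    """Result of :func:`validate_xor`: a flag plus human-readable violations."""

    is_xor: bool
    violations: tuple[str, ...]


def validate_xor(design: DesignSpec) -> XorReport:
    """Check the exclusive-or structure of a triplet design.

    The design is XOR iff (a) every design triplet has second-order TP 1 —
    the third item is fully determined by the first two — and (b) for every
    triplet the third item is *not* fully determined by the second item alone
    (positional ``p(third|second) < 1``) nor by the first alone
    (non-adjacent ``p(third|first) < 1``).
    """
    violations: list[str] = []
    for s, _ in design.items():
        if len(s) != 3:
            violations.append(f"sequence {seq_label(s)} is not a triplet")
    if violations:
        return XorReport(False, tuple(violations))
    for s, _ in design.items():
        x, y, z = s
        p2 = second_order_tp(design, x, y, z)
        if abs(p2 - 1.0) > _TOL:
            violations.append(f"p({z}|{x},{y}) = {p2:.3f} != 1")
        p_y = first_order_tp(design, y, z, (2, 3))
        if p_y >= 1.0 - _TOL:
            violations.append(f"p({z}|{y}) = 1: third item predicted by second alone")
        p_x = nonadjacent_tp(design, x, z)
        if p_x >= 1.0 - _TOL:
            violations.append(f"p({z}|{x}) = 1: third item predicted by first alone")
    return XorReport(not violations, tuple(violations))


def build_switch(design: DesignSpec) -> DesignSpec:
    """Construct the switch-phase design by permuting third items.

    The switched design (i) preserves exactly the set of adjacent ordered item
    pairs at both position pairs, (ii) shares no triplet with the original,
    (iii) gives each switched triplet the frequency of the original triplet
    with the same first two items, and (iv) is itself a valid XOR.  For the
    canonical unbalanced design {ABC, AEF, DBF, DEC} the unique solution is
    {ABF, AEC, DBC, DEF}.

    Raises
    ------
    ValueError
        If the input is not a valid XOR design.
    NoValidSwitchError
        If no permutation of third items satisfies the constraints.
    """
    report = validate_xor(design)
    if not report.is_xor:
        raise ValueError(
            "build_switch requires a valid XOR design; violations: "
            + "; ".join(report.violations)
        )
    orig = design.sequences
    n = len(orig)
    orig_set = set(orig)
    pairs23 = sorted((s[1], s[2]) for s in orig)
    candidates: list[DesignSpec] = []
    for perm in itertools.permutations(range(n)):
        new = tuple((orig[i][0], orig[i][1], orig[perm[i]][2]) for i in range(n))
        if any(t in orig_set for t in new):
            continue
        if any(len(set(t)) != 3 for t in new):
            continue
        if len(set(new)) != n:
            continue
        if sorted((t[1], t[2]) for t in new) != pairs23:
            continue
        try:
            cand = DesignSpec(new, design.frequencies)
        except ValueError:
            continue
        if validate_xor(cand).is_xor:
            candidates.append(cand)
    if not candidates:
        raise NoValidSwitchError(
            "no permutation of third items yields a pair-preserving XOR switch"
        )
    candidates.sort(key=lambda d: d.labels)
    return candidates[0]


def switch_tp_report(design: DesignSpec) -> pd.DataFrame:
    """Side-by-side positional first-order TPs of a design and its switch.

    The switch preserves the *inventory* of adjacent pairs, but because the
    switched triplets inherit the frequencies of their new prefixes, the
    position 2->3 TP *values* attached to those pairs generally change (e.g.
    F|B moves from .38 to .62 in the canonical design).  This table makes the
    discrepancy explicit rather than resolving it either way: rows with
    ``changed=True`` are pairs whose TP value differs between phases.
    """
    switched = build_switch(design)
    rows = []
    for pos, a, b in sorted(enumerate_transitions(design)):
        p_orig = first_order_tp(design, a, b, pos)
        p_new = first_order_tp(switched, a, b, pos)
        rows.append(
            {
                "positions": f"{pos[0]}-{pos[1]}",
                "from_item": a,
                "to_item": b,
                "tp_learning": p_orig,
                "tp_switch": p_new,
                "changed": abs(p_orig - p_new) > _TOL,
            }
        )
    return pd.DataFrame(rows)


def tp_table(design: DesignSpec, decimals: int | None = 2) -> pd.DataFrame:
    """Presentation table: per-sequence frequency, positional TPs, 2nd-order TP.

    ``decimals=None`` keeps full precision; the default rounds to the two
    decimals conventionally printed.
    """
    rows = []
    for s, f in design.items():
        if len(s) != 3:
            continue
        x, y, z = s
        row = {
            "sequence": seq_label(s),
            "frequency": f,
            "tp_1_2": first_order_tp(design, x, y, (1, 2)),
            "tp_2_3": first_order_tp(design, y, z, (2, 3)),
            "second_order_tp": second_order_tp(design, x, y, z),
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if decimals is not None:
        for col in ("tp_1_2", "tp_2_3", "second_order_tp"):
            df[col] = df[col].round(decimals)
    return df
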