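"""Trial-table cleaning and reshaping.

Two steps stand between a raw trial table and the mixed-model analyses:

* :func:`reshape_long` turns the wide per-trial table (one row per trial with
  ``tt1``/``tt2``) into the long format the models consume — one row per
  (trial, transition) with the design covariates (sequence frequency and the
  transition-specific first-order TP) attached;
* :func:`filter_rts` removes response-time outliers, by default everything
  outside the fixed [150, 850] ms window (bounds inclusive), with a
  mean +/- k*SD window as an alternative mode.

The filter reports what it removed, overall and per transition type, so the
"fraction of data removed" bookkeeping is always explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, first_order_tp

__all__ = ["FilterConfig", "RemovalReport", "filter_rts", "reshape_long"]


@dataclass(frozen=True)
class FilterConfig:
    """Outlier-filter settings.

    ``fixed_window`` keeps RT in ``[low_ms, high_ms]`` inclusive (default
    150-850 ms).  ``sd_window`` keeps RT within ``mean +/- sd_multiplier * SD``
    computed over the supplied table, separately per transition type when a
    ``transition`` column is present and globally otherwise.
    """

    low_ms: float = 150.0
    high_ms: float = 850.0
    mode: str = "fixed_window"
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.low_ms >= self.high_ms:
            raise ValueError("low_ms must be below high_ms")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.mode not in ("fixed_window", "sd_window"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass
class RemovalReport:
    """What an RT filter removed, overall and per transition type."""

    n_input: int
    n_kept: int
    n_removed: int
    fraction_removed: float
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    by_transition: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "fraction_removed": self.fraction_removed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "by_transition": self.by_transition,
        }


def filter_rts(
    records: pd.DataFrame, config: FilterConfig | None = None, rt_col: str = "rt"
) -> tuple[pd.DataFrame, RemovalReport]:
    """Remove RT outliers from a long trial table.

    Returns the kept rows (original order and index preserved) and a
    :class:`RemovalReport`.  An empty input yields an empty output with a
    zero-count report.
    """
    config = config or FilterConfig()
    n = len(records)
    if n == 0:
        return records.copy(), RemovalReport(0, 0, 0, 0.0)

    rt = records[rt_col].astype(float)
    has_transition = "transition" in records.columns
    bounds: dict[str, tuple[float, float]] = {}
    if config.mode == "fixed_window":
        bounds["all"] = (config.low_ms, config.high_ms)
        keep = rt.between(config.low_ms, config.high_ms)
    else:
        if has_transition:
            keep = pd.Series(False, index=records.index)
            for name, grp in records.groupby("transition"):
                mu, sd = grp[rt_col].mean(), grp[rt_col].std(ddof=1)
                sd = 0.0 if not np.isfinite(sd) else sd
                lo, hi = mu - config.sd_multiplier * sd, mu + config.sd_multiplier * sd
                bounds[str(name)] = (lo, hi)
                keep.loc[grp.index] = grp[rt_col].between(lo, hi)
        else:
            mu, sd = rt.mean(), rt.std(ddof=1)
            sd = 0.0 if not np.isfinite(sd) else sd
            lo, hi = mu - config.sd_multiplier * sd, mu + config.sd_multiplier * sd
            bounds["all"] = (lo, hi)
            keep = rt.between(lo, hi)

    kept = records[keep]
    by_transition: dict[str, dict[str, float]] = {}
    if has_transition:
        for name, grp in records.groupby("transition"):
            removed = int((~keep.loc[grp.index]).sum())
            by_transition[str(name)] = {
                "n": int(len(grp)),
                "removed": removed,
                "fraction": removed / len(grp),
            }
    report = RemovalReport(
        n_input=n,
        n_kept=int(keep.sum()),
        n_removed=int(n - keep.sum()),
        fraction_removed=float((n - keep.sum()) / n),
        bounds=bounds,
        by_transition=by_transition,
    )
    return kept, report


def reshape_long(records: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """One row per (trial, transition) with design covariates attached.

    Each trial contributes a ``TT1`` and a ``TT2`` row.  The covariates are

    * ``frequency`` — the presentation frequency of the trial's sequence; a
      switch-phase triplet inherits the frequency of the learning triplet that
      shares its first two items (which is how switch frequencies are built);
    * ``tp`` — the first-order TP of the transition the row measures,
      evaluated on the *learning-phase* design: positions 1->2 for TT1 rows
      and 2->3 for TT2 rows.  Switch triplets recombine pairs that all exist
      in the learning design, so the covariate is the TP of that pair as
      experienced during learning.

    The reshape is lossless: pivoting the ``rt`` column back on
    (participant, trial) reproduces the wide table.
    """
    required = {"item1", "item2", "item3", "tt1", "tt2"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table is missing columns: {sorted(missing)}")

    tp12: dict[tuple[str, str], float] = {}
    tp23: dict[tuple[str, str], float] = {}
    freq_by_prefix: dict[tuple[str, str], float] = {}
    for s, f in design.items():
        if len(s) < 3:
            continue
        tp12[(s[0], s[1])] = first_order_tp(design, s[0], s[1], (1, 2))
        tp23[(s[1], s[2])] = first_order_tp(design, s[1], s[2], (2, 3))
        freq_by_prefix[(s[0], s[1])] = f

    id_cols = [c for c in records.columns if c not in ("tt1", "tt2")]
    long = records.melt(
        id_vars=id_cols,
        value_vars=["tt1", "tt2"],
        var_name="transition",
        value_name="rt",
    )
    long["transition"] = long["transition"].map({"tt1": "TT1", "tt2": "TT2"})

    def row_tp(row) -> float:
        if row["transition"] == "TT1":
            return tp12.get((row["item1"], row["item2"]), float("nan"))
        return tp23.get((row["item2"], row["item3"]), float("nan"))

    long["tp"] = long.apply(row_tp, axis=1)
    long["frequency"] = [
        freq_by_prefix.get((a, b), float("nan"))
        for a, b in zip(long["item1"], long["item2"])
    ]
    sort_cols = [c for c in ("participant", "trial", "transition") if c in long.columns]
    return long.sort_values(sort_cols, kind="stable").reset_index(drop=True)
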