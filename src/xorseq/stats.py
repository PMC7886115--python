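"""Learning curves, mixed-effects contrasts, and AIC model comparison.

Response times are modelled at the trial level with linear mixed-effects
models carrying a random intercept per participant — the minimal structure
consistent with repeated measures — fitted by REML through
:mod:`statsmodels` ``MixedLM``.  Each fixed-effect term is tested with a Wald
F statistic built from the fixed-effects covariance, using the residual
degrees-of-freedom approximation ``nobs - k_fixed``; an approximate sum of
squares ``F * num_df * sigma^2`` is reported alongside so the tables read
like conventional mixed-model ANOVA output.  AICs are always taken from a
maximum-likelihood refit so that models with different fixed effects are
comparable.

:func:`run_planned_contrasts` bundles the analysis surface of the XOR
sequence-learning experiment: the global TT1-vs-TT2 contrast, first-block
effects, per-transition block (learning) effects, the equal-frequency TT1
contrast that isolates first-order TP, the TP-versus-frequency TT1 contrast,
the switch-phase TT2 cost, the block-by-TP interaction on TT2, and the
lowest-TP follow-ups.  :func:`compare_models_aic` ranks the three candidate
TT2 learning-curve models (block x frequency, block x TP, block x both).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence as SequenceT

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "TermTest",
    "ModelFitResult",
    "ContrastSpec",
    "ModelComparison",
    "aggregate_learning_curves",
    "fit_mixed_model",
    "run_planned_contrasts",
    "compare_models_aic",
    "results_to_frame",
    "plot_learning_curves",
]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_learning_curves(long: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error per (phase, block, sequence, transition) cell.

    The output covers the full grid of observed (phase, block) pairs crossed
    with observed sequences and transition types; cells with no data are kept
    with ``n = 0`` and NaN mean so that gaps are visible rather than silent.
    """
    keys = ["phase", "block", "seq", "transition"]
    g = long.groupby(keys)["rt"].agg(["mean", "std", "count"]).reset_index()
    g["se"] = g["std"] / np.sqrt(g["count"].clip(lower=1))
    g = g.rename(columns={"count": "n"}).drop(columns="std")

    phase_blocks = long[["phase", "block"]].drop_duplicates()
    seqs = long["seq"].unique()
    trans = long["transition"].unique()
    full = (
        phase_blocks.merge(pd.DataFrame({"seq": seqs}), how="cross")
        .merge(pd.DataFrame({"transition": trans}), how="cross")
    )
    out = full.merge(g, on=keys, how="left")
    out["n"] = out["n"].fillna(0).astype(int)
    out["is_empty"] = out["n"] == 0
    return out.sort_values(keys, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermTest:
    """Wald F test of one fixed-effect term."""

    term: str
    ss: float
    num_df: int
    den_df: int
    fvalue: float
    pvalue: float


@dataclass
class ModelFitResult:
    """A fitted mixed model: per-term F tests, ML-based AIC, convergence flag."""

    label: str
    formula: str
    terms: dict[str, TermTest] = field(default_factory=dict)
    primary_term: str | None = None
    aic: float = float("nan")
    converged: bool = False
    n_obs: int = 0
    n_groups: int = 0
    error: str | None = None

    @property
    def primary(self) -> TermTest | None:
        if self.primary_term is None:
            return None
        return self.terms.get(self.primary_term)


@dataclass(frozen=True)
class ContrastSpec:
    """A named subset-plus-model recipe.

    ``phases``, ``blocks``, ``transitions`` and ``sequences`` restrict the
    long table (``None`` means no restriction); ``formula`` is the
    fixed-effects model fitted on the subset with a participant random
    intercept, and ``primary_term`` names the term whose F test answers the
    contrast's question.
    """

    name: str
    formula: str
    primary_term: str
    phases: tuple[str, ...] | None = None
    blocks: tuple[int, ...] | None = None
    transitions: tuple[str, ...] | None = None
    sequences: tuple[str, ...] | None = None

    def subset(self, long: pd.DataFrame) -> pd.DataFrame:
        df = long
        if self.phases is not None:
            df = df[df["phase"].isin(self.phases)]
        if self.blocks is not None:
            df = df[df["block"].isin(self.blocks)]
        if self.transitions is not None:
            df = df[df["transition"].isin(self.transitions)]
        if self.sequences is not None:
            df = df[df["seq"].isin(self.sequences)]
        return df.copy()


def fit_mixed_model(
    data: pd.DataFrame,
    formula: str,
    *,
    groups: str = "participant",
    label: str | None = None,
    primary_term: str | None = None,
    reml: bool = True,
    ml_aic: bool = True,
) -> ModelFitResult:
    """Fit a random-intercept mixed model and test each fixed-effect term.

    Raises ``ValueError`` if fewer than two participants are present (a
    participant random intercept is undefined otherwise).  Singular or
    non-converged fits are returned with ``converged=False`` rather than
    raising.
    """
    label = label or formula
    n_groups = int(data[groups].nunique()) if groups in data.columns else 0
    if n_groups < 2:
        raise ValueError(
            f"mixed model needs >= 2 levels of {groups!r}, got {n_groups}"
        )
    result = ModelFitResult(label=label, formula=formula, primary_term=primary_term)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=groups)
            res = model.fit(reml=reml)
            res_ml = res if not reml else (model.fit(reml=False) if ml_aic else None)
    except (np.linalg.LinAlgError, ValueError) as exc:
        result.error = str(exc)
        return result

    k_fe = len(res.fe_params)
    n_obs = int(model.exog.shape[0])
    den_df = max(n_obs - k_fe, 1)
    fe = np.asarray(res.fe_params, dtype=float)
    cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]
    terms: dict[str, TermTest] = {}
    term_slices = model.data.design_info.term_name_slices
    for term, slc in term_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(k_fe)[slc]
        b = fe[idx]
        V = cov_fe[np.ix_(idx, idx)]
        q = len(idx)
        try:
            stat = float(b @ np.linalg.solve(V, b)) / q
        except np.linalg.LinAlgError:
            stat = float("nan")
        p = float(scipy.stats.f.sf(stat, q, den_df)) if np.isfinite(stat) else float("nan")
        terms[term] = TermTest(
            term=term,
            ss=float(stat * q * res.scale),
            num_df=q,
            den_df=den_df,
            fvalue=stat,
            pvalue=p,
        )

    if res_ml is not None:
        aic = float(res_ml.aic)
        if not np.isfinite(aic):
            aic = float(-2.0 * res_ml.llf + 2.0 * (len(res_ml.params) + 1))
    else:
        aic = float("nan")

    result.terms = terms
    result.aic = aic
    result.converged = bool(res.converged) and np.all(np.isfinite(fe))
    result.n_obs = n_obs
    result.n_groups = n_groups
    return result


def _fit_contrast(long: pd.DataFrame, spec: ContrastSpec, groups: str) -> ModelFitResult:
    df = spec.subset(long)
    if df.empty or (groups in df.columns and df[groups].nunique() < 2):
        return ModelFitResult(
            label=spec.name,
            formula=spec.formula,
            primary_term=spec.primary_term,
            error="subset is empty or has fewer than two participants",
        )
    try:
        return fit_mixed_model(
            df,
            spec.formula,
            groups=groups,
            label=spec.name,
            primary_term=spec.primary_term,
            ml_aic=False,
        )
    except ValueError as exc:
        return ModelFitResult(
            label=spec.name,
            formula=spec.formula,
            primary_term=spec.primary_term,
            error=str(exc),
        )


def _sequence_info(long: pd.DataFrame) -> pd.DataFrame:
    """Per-sequence frequency and transition-specific TPs from the long table."""
    learn = long[long["phase"] == "learning"]
    tp1 = learn[learn["transition"] == "TT1"].groupby("seq")["tp"].first()
    tp2 = learn[learn["transition"] == "TT2"].groupby("seq")["tp"].first()
    freq = learn.groupby("seq")["frequency"].first()
    return pd.DataFrame({"tp1": tp1, "tp2": tp2, "frequency": freq})


def run_planned_contrasts(
    long: pd.DataFrame, groups: str = "participant"
) -> list[ModelFitResult]:
    """The full analysis surface of the XOR experiment on a cleaned long table.

    Contrast selection is driven by the covariates in the table itself: the
    equal-frequency pair is the (unique) pair of sequences sharing a
    frequency, the TP-versus-frequency pair opposes the highest-TP1 sequence
    to the most frequent one, and the lowest-TP sequence is the one with the
    smallest TT2-transition TP.  Contrasts whose subset is missing come back
    as error entries instead of raising.
    """
    info = _sequence_info(long)
    learn_blocks = sorted(long.loc[long["phase"] == "learning", "block"].unique())
    last_block = learn_blocks[-1] if learn_blocks else None
    has_switch = bool((long["phase"] == "switch").any())

    freq_counts = info["frequency"].value_counts()
    equal_pair: tuple[str, ...] | None = None
    for f, c in freq_counts.items():
        if c == 2:
            equal_pair = tuple(info.index[info["frequency"] == f])
            break
    top_tp = info["tp1"].idxmax()
    top_freq = info["frequency"].idxmax()
    tp_vs_freq_pair = (top_tp, top_freq) if top_tp != top_freq else None
    lowest = info["tp2"].idxmin()
    high_three = tuple(info.index[info.index != lowest])

    specs: list[ContrastSpec] = [
        ContrastSpec(
            "transition_type", "rt ~ C(transition)", "C(transition)",
            phases=("learning",),
        ),
        ContrastSpec(
            "first_block_tp", "rt ~ C(transition) * C(tp)", "C(tp)",
            phases=("learning",), blocks=(learn_blocks[0],) if learn_blocks else None,
        ),
        ContrastSpec(
            "block_tt1", "rt ~ block", "block",
            phases=("learning",), transitions=("TT1",),
        ),
        ContrastSpec(
            "block_tt2", "rt ~ block", "block",
            phases=("learning",), transitions=("TT2",),
        ),
    ]
    if equal_pair is not None:
        specs.append(
            ContrastSpec(
                "equal_freq_tt1", "rt ~ block * C(tp)", "block:C(tp)",
                phases=("learning",), transitions=("TT1",), sequences=equal_pair,
            )
        )
    if tp_vs_freq_pair is not None:
        specs.append(
            ContrastSpec(
                "tp_vs_freq_tt1", "rt ~ block * C(tp)", "block:C(tp)",
                phases=("learning",), transitions=("TT1",), sequences=tp_vs_freq_pair,
            )
        )
    if has_switch and last_block is not None:
        specs.append(
            ContrastSpec(
                "switch_cost_tt2", "rt ~ C(phase, Treatment('learning'))",
                "C(phase, Treatment('learning'))",
                phases=("learning", "switch"), transitions=("TT2",),
                blocks=(last_block, last_block + 1),
            )
        )
    specs.append(
        ContrastSpec(
            "block_by_tp_tt2", "rt ~ block * C(tp)", "block:C(tp)",
            phases=("learning",), transitions=("TT2",),
        )
    )
    specs.append(
        ContrastSpec(
            "high_tp_equiv_tt2", "rt ~ block + C(tp)", "C(tp)",
            phases=("learning",), transitions=("TT2",), sequences=high_three,
        )
    )

    results = [_fit_contrast(long, spec, groups) for spec in specs]

    # lowest-TP sequence versus the three others on TT2
    sub = long[(long["phase"] == "learning") & (long["transition"] == "TT2")].copy()
    if not sub.empty:
        sub["lowest"] = sub["seq"] == lowest
        results.append(
            _fit_contrast(
                sub,
                ContrastSpec("lowest_tp_tt2", "rt ~ C(lowest)", "C(lowest)"),
                groups,
            )
        )
    if has_switch and last_block is not None:
        spec = ContrastSpec(
            "lowest_tp_switch_tt2", "rt ~ C(phase, Treatment('learning'))",
            "C(phase, Treatment('learning'))",
            phases=("learning", "switch"), transitions=("TT2",),
            blocks=(last_block, last_block + 1),
        )
        sub2 = spec.subset(long)
        switched_lowest = sub2.loc[
            (sub2["phase"] == "switch")
            & sub2["seq"].str.startswith(str(lowest)[:2]), "seq",
        ].unique()
        wanted = {lowest, *switched_lowest}
        sub2 = sub2[sub2["seq"].isin(wanted)]
        results.append(
            _fit_contrast(
                sub2,
                ContrastSpec(
                    "lowest_tp_switch_tt2", spec.formula, spec.primary_term
                ),
                groups,
            )
        )
    return results


# ---------------------------------------------------------------------------
# AIC comparison
# ---------------------------------------------------------------------------

DEFAULT_AIC_FORMULAS: dict[str, str] = {
    "block*frequency": "rt ~ block * frequency",
    "block*tp": "rt ~ block * tp",
    "block*frequency*tp": "rt ~ block * frequency * tp",
}


@dataclass
class ModelComparison:
    """AIC-ordered candidate models; ties (within ``tie_tol``) reported as ties."""

    results: list[ModelFitResult]
    tie_tol: float = 1e-6

    @property
    def aics(self) -> dict[str, float]:
        return {r.label: r.aic for r in self.results}

    @property
    def ranking(self) -> list[str]:
        order = sorted(self.results, key=lambda r: (np.isnan(r.aic), r.aic))
        return [r.label for r in order]

    @property
    def ties(self) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.results):
            for b in self.results[i + 1:]:
                if np.isfinite(a.aic) and abs(a.aic - b.aic) <= self.tie_tol:
                    out.append((a.label, b.label))
        return out

    @property
    def best(self) -> str:
        return self.ranking[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model": r.label,
                    "formula": r.formula,
                    "aic": r.aic,
                    "converged": r.converged,
                }
                for r in sorted(self.results, key=lambda r: (np.isnan(r.aic), r.aic))
            ]
        )


def compare_models_aic(
    long: pd.DataFrame,
    formulas: dict[str, str] | None = None,
    groups: str = "participant",
) -> ModelComparison:
    """Compare candidate TT2 learning-curve models by maximum-likelihood AIC.

    All models are fitted on the identical learning-phase TT2 subset with
    numeric ``frequency`` and ``tp`` covariates (numeric coding keeps the
    frequency-and-TP model full rank; the two covariates are distinct across
    sequences but not collinear).  Lower AIC is better.
    """
    formulas = formulas or DEFAULT_AIC_FORMULAS
    df = long
    if "transition" in df.columns:
        df = df[df["transition"] == "TT2"]
    if "phase" in df.columns:
        df = df[df["phase"] == "learning"]
    df = df.copy()
    if df.empty:
        raise ValueError("no learning-phase TT2 rows to fit")
    results = [
        fit_mixed_model(df, formula, groups=groups, label=label, reml=False)
        for label, formula in formulas.items()
    ]
    return ModelComparison(results)


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------


def results_to_frame(results: SequenceT[ModelFitResult]) -> pd.DataFrame:
    """Tidy table of term tests across fitted models."""
    rows = []
    for r in results:
        if r.error is not None:
            rows.append(
                {
                    "model": r.label, "term": None, "ss": np.nan, "num_df": np.nan,
                    "den_df": np.nan, "fvalue": np.nan, "pvalue": np.nan,
                    "primary": False, "converged": r.converged, "error": r.error,
                }
            )
            continue
        for t in r.terms.values():
            rows.append(
                {
                    "model": r.label, "term": t.term, "ss": t.ss,
                    "num_df": t.num_df, "den_df": t.den_df, "fvalue": t.fvalue,
                    "pvalue": t.pvalue, "primary": t.term == r.primary_term,
                    "converged": r.converged, "error": None,
                }
            )
    return pd.DataFrame(rows)


def plot_learning_curves(curves: pd.DataFrame, path=None):
    """Learning-curve figure: mean RT per block and sequence, TT1 and TT2 panels.

    Switch-phase blocks are drawn as detached points after the learning
    curves.  Returns the Matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib.pyplot as plt

    transitions = [t for t in ("TT1", "TT2") if t in set(curves["transition"])]
    fig, axes = plt.subplots(
        1, max(len(transitions), 1), figsize=(5.0 * max(len(transitions), 1), 4.0),
        sharey=True, squeeze=False,
    )
    for ax, trans in zip(axes[0], transitions):
        sub = curves[(curves["transition"] == trans) & (~curves["is_empty"])]
        for seq, grp in sub.groupby("seq"):
            learn = grp[grp["phase"] == "learning"].sort_values("block")
            line = ax.errorbar(
                learn["block"], learn["mean"], yerr=learn["se"],
                marker="o", ms=3, capsize=2, label=str(seq),
            )
            sw = grp[grp["phase"] == "switch"].sort_values("block")
            if not sw.empty:
                ax.errorbar(
                    sw["block"], sw["mean"], yerr=sw["se"],
                    marker="s", ms=4, capsize=2, linestyle="none",
                    color=line.lines[0].get_color(),
                )
        ax.set_title(trans)
        ax.set_xlabel("block")
    axes[0][0].set_ylabel("mean RT (ms)")
    if transitions:
        axes[0][-1].legend(title="sequence", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
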