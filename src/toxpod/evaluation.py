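"""Model scoring and the cross-validation harness.

Two statistics run through everything: RMSE (log10 mg/kg/day) and the
pseudo-R², defined as 1 - MSE / Var(observed) with the population (1/n)
variance convention — it can go negative for models worse than predicting
the observed mean. Scoring happens at two levels: per study, and per
chemical using the minimum observed vs minimum predicted effect level
across a chemical's studies (the decision-relevant aggregation).

``run_cv`` executes the full chemical-grouped k-fold x repeat design for a
modeling table: fit on the training chemicals' studies, bias-correct with
fold-local coefficients, score on the held-out chemicals' studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EffectLevelForest, ModelingTable
from .splitting import SplitPlan
from .study import InputError

__all__ = [
    "EvalReport",
    "CVResult",
    "rmse",
    "pseudo_r2",
    "within_one_log_fraction",
    "chemical_level_eval",
    "run_cv",
    "evaluate_external",
]


def _check_lengths(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InputError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise InputError("empty vectors")
    return obs, pred


def rmse(observed, predicted) -> float:
    """Root mean squared error."""
    obs, pred = _check_lengths(observed, predicted)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pseudo_r2(observed, predicted, ddof: int = 0) -> float:
    """1 - MSE / Var(observed); population variance by default."""
    obs, pred = _check_lengths(observed, predicted)
    var = float(np.var(obs, ddof=ddof))
    if var <= 0:
        raise InputError("observed values have zero variance")
    return float(1.0 - np.mean((pred - obs) ** 2) / var)


def within_one_log_fraction(observed, predicted) -> float:
    """Fraction of predictions within one order of magnitude (|Δ| <= 1)."""
    obs, pred = _check_lengths(observed, predicted)
    return float(np.mean(np.abs(pred - obs) <= 1.0 + 1e-12))


@dataclass
class EvalReport:
    """Scores plus per-row observed/predicted pairs for one split cell."""

    level: str  # study | chemical
    tier: str
    split: str  # e.g. "cv r2 f1" or "external"
    n: int
    rmse: float
    r2: float
    fraction_within_1log: float
    frame: pd.DataFrame  # observed, predicted (+ chemical_id at study level)

    @classmethod
    def from_pairs(cls, frame: pd.DataFrame, level: str, tier: str, split: str) -> "EvalReport":
        obs, pred = frame["observed"], frame["predicted"]
        return cls(
            level=level,
            tier=tier,
            split=split,
            n=len(frame),
            rmse=rmse(obs, pred),
            r2=pseudo_r2(obs, pred),
            fraction_within_1log=within_one_log_fraction(obs, pred),
            frame=frame,
        )


def chemical_level_eval(study_report: EvalReport) -> EvalReport:
    """Aggregate a study-level report to chemicals via min-min pairing.

    Per chemical: minimum observed vs minimum predicted effect level over
    its studies — the comparison a screening decision would use.
    """
    frame = study_report.frame
    if "chemical_id" not in frame:
        raise InputError("study-level report lacks chemical ids")
    pairs = (
        frame.groupby("chemical_id")[["observed", "predicted"]]
        .min()
        .reset_index()
    )
    return EvalReport.from_pairs(pairs, "chemical", study_report.tier, study_report.split)


@dataclass
class CVResult:
    """All CV cells of one tier: scores, bias coefficients, predictions."""

    tier: str
    scores: pd.DataFrame  # repeat, fold, n, rmse, r2, frac..., bias_slope/intercept
    predictions: pd.DataFrame  # repeat, fold, study_id, chemical_id, observed, predicted

    @property
    def median_r2(self) -> float:
        return float(self.scores["r2"].median())

    @property
    def median_rmse(self) -> float:
        return float(self.scores["rmse"].median())

    def mean_bias(self) -> tuple[float, float]:
        """Mean of fold-level (slope, intercept) — used by final models."""
        return float(self.scores["bias_slope"].mean()), float(self.scores["bias_intercept"].mean())


def run_cv(
    table: ModelingTable,
    plan: SplitPlan,
    ntree: int = 250,
    seed: int = 0,
) -> CVResult:
    """Chemical-grouped cross-validation of one modeling table.

    For every (repeat, fold) cell: fit on the internal training chemicals'
    studies, bias-correct with the cell's own training coefficients, and
    score the held-out chemicals' studies. Rows inherit their chemical's
    assignment, so no chemical ever spans train and test.
    """
    internal = table.subset_chemicals(plan.internal_chemicals)
    score_rows, pred_frames = [], []
    for rep, fold in plan.cells():
        test_chems = plan.folds[(rep, fold)] & set(internal.frame["chemical_id"])
        train_chems = plan.train_chemicals(rep, fold)
        if len(test_chems) < 2:
            raise InputError(f"fold ({rep}, {fold}) has fewer than 2 chemicals with data")
        train = internal.subset_chemicals(train_chems)
        test = internal.subset_chemicals(test_chems)
        cell_seed = int(np.random.SeedSequence([seed, rep, fold]).generate_state(1)[0] % (2**31))
        res = EffectLevelForest(train).fit(ntree=ntree, seed=cell_seed)
        pred = res.predict(test.frame, bias_corrected=True)
        cell = pd.DataFrame(
            {
                "repeat": rep,
                "fold": fold,
                "study_id": test.frame["study_id"],
                "chemical_id": test.frame["chemical_id"],
                "observed": test.response.to_numpy(),
                "predicted": pred,
            }
        )
        pred_frames.append(cell)
        score_rows.append(
            {
                "repeat": rep,
                "fold": fold,
                "n": len(cell),
                "rmse": rmse(cell["observed"], cell["predicted"]),
                "r2": pseudo_r2(cell["observed"], cell["predicted"]),
                "fraction_within_1log": within_one_log_fraction(cell["observed"], cell["predicted"]),
                "bias_slope": res.bias_slope,
                "bias_intercept": res.bias_intercept,
            }
        )
    return CVResult(
        tier=table.tier,
        scores=pd.DataFrame(score_rows),
        predictions=pd.concat(pred_frames, ignore_index=True),
    )


def evaluate_external(results, table: ModelingTable, plan: SplitPlan) -> EvalReport:
    """Score a fitted (final) model on the external hold-out studies."""
    ext = table.subset_chemicals(plan.external_chemicals)
    if ext.frame.empty:
        raise InputError("no external studies for this tier")
    pred = results.predict(ext.frame, bias_corrected=True)
    frame = pd.DataFrame(
        {
            "study_id": ext.frame["study_id"],
            "chemical_id": ext.frame["chemical_id"],
            "observed": ext.response.to_numpy(),
            "predicted": pred,
        }
    )
    return EvalReport.from_pairs(frame, "study", table.tier, "external")


def r2_dotplot(cv_results: dict[str, CVResult], path) -> None:
    """Dot plot of per-cell CV R² by tier, crossbar at the tier median."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for i, (tier, cv) in enumerate(cv_results.items()):
        y = cv.scores["r2"]
        x = np.full(len(y), i) + np.linspace(-0.15, 0.15, len(y))
        ax.plot(x, y, "o", alpha=0.6, label=None)
        ax.hlines(y.median(), i - 0.25, i + 0.25, color="0.3")
    ax.set_xticks(range(len(cv_results)), list(cv_results))
    ax.set_ylabel("cross-validated pseudo-$R^2$")
    ax.set_xlabel("model tier")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pred_obs_scatter(report: EvalReport, path) -> None:
    """Predicted-vs-observed scatter with the identity and ±1 log bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.frame["observed"], report.frame["predicted"], "o", alpha=0.4, ms=3)
    lims = (-2, 4)
    ax.plot(lims, lims, "k-", lw=1)
    for off in (-1, 1):
        ax.plot(lims, [lims[0] + off, lims[1] + off], "k--", lw=0.7)
    ax.set_xlim(lims)
    ax.set_ylim(lims)
    ax.set_xlabel("observed effect level (log10 mg/kg/day)")
    ax.set_ylabel("predicted effect level (log10 mg/kg/day)")
    ax.set_title(f"{report.tier} / {report.split}: $R^2$={report.r2:.2f}, RMSE={report.rmse:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
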