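"""Forward predictions for chemicals without in vivo studies.

A study-level model needs study covariates, which a new chemical does not
have. The scheme: sample N mock study designs per chemical from the pool of
covariate combinations observed in studies where a LOAEL was established,
combine each with the chemical's descriptors, predict, and summarise the
per-chemical distribution by its minimum, mean and SD. Uncertainty is
attached globally as ± the deployed tier's external-test RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ForestResults, COVARIATES
from .study import InputError

__all__ = ["ForwardResult", "observed_covariate_pool", "forward_predict", "forward_predict_cascade"]


@dataclass
class ForwardResult:
    """Chemical-level forward prediction summary."""

    chemical_id: str
    tier: str
    predictions: np.ndarray  # one per mock study
    pred_min: float
    pred_mean: float
    pred_sd: float
    uncertainty: float  # half-width = external RMSE of the deployed tier

    @property
    def lower(self) -> float:
        return self.pred_min - self.uncertainty

    @property
    def upper(self) -> float:
        return self.pred_min + self.uncertainty


def observed_covariate_pool(effects: pd.DataFrame) -> pd.DataFrame:
    """Unique covariate combinations from studies with an established LOAEL.

    Deterministically ordered (sorted over all eight covariates) and
    deduplicated; raises when the registry has no LOAEL studies.
    """
    pool = effects.loc[effects["pod_type"] == "LOAEL", list(COVARIATES)]
    pool = pool.drop_duplicates().sort_values(list(COVARIATES), ignore_index=True)
    if pool.empty:
        raise InputError("no LOAEL studies: empty covariate pool")
    return pool


def forward_predict(
    chemicals: list[str],
    descriptor_rows: pd.DataFrame | None,
    fit: ForestResults,
    pool: pd.DataFrame,
    n_mock: int = 5,
    seed: int = 0,
    external_rmse: float = float("nan"),
) -> list[ForwardResult]:
    """Predict chemical-level effect levels via mock-study sampling.

    For each chemical, ``n_mock`` covariate combinations are sampled from the
    pool (without replacement when the pool is large enough) and combined
    with the chemical's descriptor row; the fitted model predicts each mock
    study. Total prediction count is exactly ``len(chemicals) * n_mock``.
    """
    if n_mock < 1:
        raise InputError("n_mock must be >= 1")
    table = fit.model.table
    desc_cols = [c for c in table.predictors if c not in COVARIATES and c != "podmn"]
    if desc_cols:
        if descriptor_rows is None:
            raise InputError(f"tier {fit.tier!r} requires descriptor columns {desc_cols[:5]}...")
        missing_cols = [c for c in desc_cols if c not in descriptor_rows.columns]
        if missing_cols:
            raise InputError(f"descriptor rows lack columns: {missing_cols[:10]}")
        missing_chems = [c for c in chemicals if c not in descriptor_rows.index]
        if missing_chems:
            raise InputError(f"chemicals lack descriptor rows: {missing_chems[:10]}")
    if "podmn" in table.predictors:
        raise InputError("benchmark tier cannot be deployed forward (podmn needs in vivo data)")

    encoded_pool = table.encode_covariates(pool).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    replace = len(encoded_pool) < n_mock
    picks = np.concatenate(
        [rng.choice(len(encoded_pool), size=n_mock, replace=replace) for _ in chemicals]
    )
    rows = encoded_pool.iloc[picks].reset_index(drop=True)
    if desc_cols:
        desc = descriptor_rows.loc[np.repeat(chemicals, n_mock), desc_cols].reset_index(drop=True)
        rows = pd.concat([rows, desc], axis=1)
    preds = fit.predict(rows, bias_corrected=True)  # one batched forest call
    results = []
    for i, chem in enumerate(chemicals):
        p = preds[i * n_mock : (i + 1) * n_mock]
        results.append(
            ForwardResult(
                chemical_id=chem,
                tier=fit.tier,
                predictions=p,
                pred_min=float(p.min()),
                pred_mean=float(p.mean()),
                pred_sd=float(p.std()),
                uncertainty=float(external_rmse),
            )
        )
    return results


def forward_predict_cascade(
    chemical_blocks: dict[str, list[str]],
    descriptor_rows: pd.DataFrame | None,
    fits: dict[str, ForestResults],
    pool: pd.DataFrame,
    n_mock: int = 5,
    seed: int = 0,
    external_rmse: dict[str, float] | None = None,
) -> list[ForwardResult]:
    """Deploy each chemical on the richest tier its blocks support.

    ``chemical_blocks`` maps tier name -> chemicals to run on that tier
    (already cascaded by the caller's availability bookkeeping); ``fits``
    maps tier -> fitted model.
    """
    external_rmse = external_rmse or {}
    out: list[ForwardResult] = []
    for tier, chems in chemical_blocks.items():
        if not chems:
            continue
        out.extend(
            forward_predict(
                chems,
                descriptor_rows,
                fits[tier],
                pool,
                n_mock=n_mock,
                seed=seed,
                external_rmse=external_rmse.get(tier, float("nan")),
            )
        )
    return out


def results_table(results: list[ForwardResult]) -> pd.DataFrame:
    """Delimited-friendly chemical-level prediction table."""
    return pd.DataFrame(
        [
            {
                "chemical_id": r.chemical_id,
                "tier": r.tier,
                "pred_min": r.pred_min,
                "pred_mean": r.pred_mean,
                "pred_sd": r.pred_sd,
                "lower": r.lower,
                "upper": r.upper,
            }
            for r in results
        ]
    )
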