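"""Random-forest effect-level models, statsmodels-style.

``assemble_table`` joins the study-level response + eight covariates with
chemical-level descriptor blocks into a :class:`ModelingTable` for one of
five predictor tiers:

* ``baseline``      — the eight study covariates only (lower variance bound);
* ``chem``          — + physchem, padel, toxprint descriptors;
* ``chem_bio``      — + bioactivity group scores;
* ``chem_bio_kin``  — + kinetic descriptors;
* ``benchmark``     — covariates + the chemical's mean observed effect level
  (``podmn``), the upper variance bound: it assumes the chemical's typical
  effect level is known and asks how much study-to-study variability the
  covariates can then absorb.

:class:`EffectLevelForest` wraps a regression forest with the conventions
used throughout: ``mtry = floor(p / 3)`` features per split, 250 trees
during cross-validation, 2500 for final models (stable importance), and a
post-hoc linear bias correction (observed-on-predicted OLS over the training
rows). ``fit()`` returns a :class:`ForestResults` carrying the forest,
bias coefficients, impurity-based variable importance and metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .descriptors import DescriptorMatrix
from .study import InputError, chemical_mean_effect

__all__ = [
    "TIERS",
    "TIER_BLOCKS",
    "ModelingTable",
    "EffectLevelForest",
    "ForestResults",
    "assemble_table",
    "mtry_for",
]

CATEGORICAL_COVARIATES = (
    "study_type",
    "species",
    "strain_group",
    "admin_method",
    "pod_type",
    "pod_qual",
)
NUMERIC_COVARIATES = ("dose_no", "dose_spacing")
COVARIATES = CATEGORICAL_COVARIATES[:4] + NUMERIC_COVARIATES + CATEGORICAL_COVARIATES[4:]

TIERS = ("baseline", "chem", "chem_bio", "chem_bio_kin", "benchmark")
TIER_BLOCKS: dict[str, tuple[str, ...]] = {
    "baseline": (),
    "chem": ("physchem", "padel", "toxprint"),
    "chem_bio": ("physchem", "padel", "toxprint", "toxcast"),
    "chem_bio_kin": ("physchem", "padel", "toxprint", "toxcast", "httk"),
    "benchmark": (),
}


def mtry_for(n_predictors: int) -> int:
    """Features considered per split: one third of p, rounded down, min 1."""
    return max(1, n_predictors // 3)


@dataclass
class ModelingTable:
    """Encoded study rows ready for fitting.

    ``frame`` holds study_id, chemical_id, the response ``value_log10`` and
    the encoded predictors; ``encodings`` records the integer code of every
    categorical level (sorted category order, mimicking factor handling) so
    new rows can be encoded consistently.
    """

    frame: pd.DataFrame
    predictors: list[str]
    tier: str
    encodings: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def response(self) -> pd.Series:
        return self.frame["value_log10"]

    def X(self) -> pd.DataFrame:
        return self.frame[self.predictors]

    def subset_chemicals(self, chemicals: Iterable[str]) -> "ModelingTable":
        chems = set(chemicals)
        return ModelingTable(
            frame=self.frame[self.frame["chemical_id"].isin(chems)].copy(),
            predictors=self.predictors,
            tier=self.tier,
            encodings=self.encodings,
        )

    def encode_covariates(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Apply this table's categorical encodings to raw covariate rows."""
        out = raw.copy()
        for col, mapping in self.encodings.items():
            if col in out:
                out[col] = out[col].map(lambda v: mapping.get(v, -1))
        return out


def _encode(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    encodings = {}
    out = frame.copy()
    for col in CATEGORICAL_COVARIATES:
        cats = sorted(out[col].astype(str).unique())
        mapping = {c: i for i, c in enumerate(cats)}
        encodings[col] = mapping
        out[col] = out[col].astype(str).map(mapping)
    return out, encodings


def block_availability(
    blocks: Mapping[str, DescriptorMatrix],
) -> dict[str, set[str]]:
    """Chemicals possessing each block (at least one observed cell)."""
    avail = {}
    for name, dm in blocks.items():
        present = dm.data.notna().any(axis=1)
        avail[name] = set(dm.data.index[present])
    return avail


def assemble_table(
    effects: pd.DataFrame,
    tier: str,
    descriptors: DescriptorMatrix | None = None,
    availability: Mapping[str, set] | None = None,
    chemical_means: pd.Series | None = None,
) -> ModelingTable:
    """Join study rows with the descriptor blocks a tier requires.

    ``effects`` is the derived effect table (one row per study with the
    response and raw covariates). Rows are restricted to chemicals
    possessing every block of the tier; the benchmark tier instead appends
    ``podmn``, the chemical mean effect level over all of its studies.
    """
    if tier not in TIERS:
        raise InputError(f"unknown tier {tier!r}; expected one of {TIERS}")
    needed = TIER_BLOCKS[tier]
    frame = effects.copy()

    if needed:
        if descriptors is None:
            raise InputError(f"tier {tier!r} requires descriptor blocks {needed}")
        avail = availability
        if avail is None:
            avail = {b: set(descriptors.chemicals) for b in needed}
        keep = set(frame["chemical_id"])
        for block in needed:
            if block not in avail:
                raise InputError(f"missing descriptor block {block!r} for tier {tier!r}")
            keep &= avail[block]
        frame = frame[frame["chemical_id"].isin(keep)]
        if frame.empty:
            raise InputError(f"empty join: no chemicals possess all blocks {needed}")

    frame, encodings = _encode(frame)
    predictors = list(COVARIATES)

    if needed:
        cols = [c for c in descriptors.data.columns if descriptors.blocks[c] in needed]
        if not cols:
            raise InputError(f"descriptor matrix has no columns for blocks {needed}")
        desc = descriptors.data.loc[:, cols]
        frame = frame.join(desc, on="chemical_id", how="inner")
        predictors += cols

    if tier == "benchmark":
        means = chemical_means if chemical_means is not None else chemical_mean_effect(effects)
        frame = frame.assign(podmn=frame["chemical_id"].map(means))
        predictors.append("podmn")

    if frame[predictors].isna().any().any():
        bad = frame[predictors].columns[frame[predictors].isna().any()]
        raise InputError(f"missing predictor values remain (impute upstream): {list(bad)[:5]}")
    return ModelingTable(frame=frame.reset_index(drop=True), predictors=predictors, tier=tier, encodings=encodings)


class EffectLevelForest:
    """Random-forest regression of study effect levels on a modeling table."""

    def __init__(self, table: ModelingTable):
        if table.response.nunique() < 2:
            raise InputError("constant response; nothing to fit")
        self.table = table

    @classmethod
    def from_tables(cls, effects: pd.DataFrame, tier: str = "baseline", **kwargs) -> "EffectLevelForest":
        return cls(assemble_table(effects, tier, **kwargs))

    def fit(self, ntree: int = 250, seed: int = 0) -> "ForestResults":
        """Fit the forest and estimate bias-correction coefficients.

        The bias correction is the OLS of observed on the forest's
        out-of-bag training predictions; test-time predictions are mapped
        through ``intercept + slope * raw``. OOB predictions (what
        ``predict`` on the training data returns in the reference forest
        ecosystem) estimate test-time behavior without memorization, so
        the coefficients correct real miscalibration rather than chasing
        the in-bag fit.
        """
        Xf = self.table.X().copy()
        y = self.table.response.to_numpy(dtype=float)
        # categorical covariates enter as their training mean response
        # (impact coding): for a regression tree the optimal binary split of
        # a factor is contiguous in mean-response order, so this reproduces
        # true factor splits that integer codes cannot express
        target_maps: dict[str, dict[int, float]] = {}
        for col in self.table.encodings:
            if col in Xf.columns:
                means = pd.Series(y, index=Xf.index).groupby(Xf[col]).mean()
                target_maps[col] = {int(k): float(v) for k, v in means.items()}
                Xf[col] = Xf[col].map(target_maps[col])
        X = Xf.to_numpy(dtype=float)
        p = len(self.table.predictors)
        # min_samples_leaf=5 is the classic regression-forest terminal node
        # size; fully-grown trees would memorize the within-chemical noise
        rf = RandomForestRegressor(
            n_estimators=ntree,
            max_features=mtry_for(p),
            min_samples_leaf=5,
            random_state=int(seed) % (2**31),
            oob_score=True,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
            warnings.filterwarnings("ignore", message="invalid value encountered")
            rf.fit(X, y)
        train_mean = float(y.mean())
        oob = np.asarray(rf.oob_prediction_, dtype=float)
        ok = np.isfinite(oob)
        if ok.sum() >= 2:
            slope, intercept = _bias_coefficients(y[ok], oob[ok])
        else:
            slope, intercept = _bias_coefficients(y, rf.predict(X))
        importance = pd.DataFrame(
            {"descriptor": self.table.predictors, "importance": rf.feature_importances_}
        ).sort_values(["importance", "descriptor"], ascending=[False, True], ignore_index=True)
        importance["rank"] = np.arange(1, len(importance) + 1)
        return ForestResults(
            model=self,
            forest=rf,
            tier=self.table.tier,
            ntree=ntree,
            mtry=mtry_for(p),
            bias_slope=slope,
            bias_intercept=intercept,
            importance=importance,
            seed=int(seed),
            target_maps=target_maps,
            train_mean=train_mean,
        )


def _bias_coefficients(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """OLS slope/intercept of observed ~ predicted; identity if degenerate."""
    if np.var(predicted) <= 0:
        warnings.warn("degenerate training predictions; bias correction is identity")
        return 1.0, 0.0
    slope, intercept = np.polyfit(predicted, observed, deg=1)
    return float(slope), float(intercept)


@dataclass
class ForestResults:
    """Fitted forest + bias coefficients + importance ranks."""

    model: EffectLevelForest
    forest: RandomForestRegressor
    tier: str
    ntree: int
    mtry: int
    bias_slope: float
    bias_intercept: float
    importance: pd.DataFrame
    seed: int
    #: per categorical predictor: integer code -> training mean response
    target_maps: dict = field(default_factory=dict)
    train_mean: float = float("nan")

    def bias_correct(self, raw_predictions) -> np.ndarray:
        raw = np.asarray(raw_predictions, dtype=float)
        return self.bias_intercept + self.bias_slope * raw

    def set_bias(self, slope: float, intercept: float) -> "ForestResults":
        """Override bias coefficients (e.g. mean of per-fold CV coefficients)."""
        self.bias_slope = float(slope)
        self.bias_intercept = float(intercept)
        return self

    def predict(self, rows: pd.DataFrame, bias_corrected: bool = True) -> np.ndarray:
        """Predict effect levels (log10 mg/kg/day) for encoded rows."""
        missing = [c for c in self.model.table.predictors if c not in rows.columns]
        if missing:
            raise InputError(f"rows lack predictors: {missing[:10]}")
        Xf = rows[self.model.table.predictors].copy()
        if Xf.isna().any().any():
            raise InputError("missing predictor values in prediction rows")
        for col, mapping in self.target_maps.items():
            # unseen categories fall back to the training mean response
            Xf[col] = Xf[col].map(mapping).fillna(self.train_mean)
        X = Xf.to_numpy(dtype=float)
        raw = self.forest.predict(X)
        return self.bias_correct(raw) if bias_corrected else raw

    def summary(self, top: int = 10) -> str:
        lines = [
            "Effect-level random forest results",
            "=" * 44,
            f"tier:            {self.tier}",
            f"n studies:       {len(self.model.table.frame)}",
            f"n chemicals:     {self.model.table.frame['chemical_id'].nunique()}",
            f"predictors (p):  {len(self.model.table.predictors)}",
            f"ntree:           {self.ntree}",
            f"mtry:            {self.mtry}",
            f"bias slope:      {self.bias_slope:.4f}",
            f"bias intercept:  {self.bias_intercept:.4f}",
            "",
            f"top {top} descriptors by node-impurity importance:",
        ]
        for row in self.importance.head(top).itertuples(index=False):
            lines.append(f"  {row.rank:>3d}  {row.descriptor:<28s} {row.importance:.4f}")
        return "\n".join(lines)

    def save(self, blob_path, meta_path) -> None:
        """Opaque model blob + structured-text sidecar metadata."""
        joblib.dump(self.forest, blob_path)
        meta = {
            "tier": self.tier,
            "ntree": self.ntree,
            "mtry": self.mtry,
            "bias_slope": self.bias_slope,
            "bias_intercept": self.bias_intercept,
            "seed": self.seed,
            "predictors": self.model.table.predictors,
            "encodings": self.model.table.encodings,
            "target_maps": self.target_maps,
            "train_mean": self.train_mean,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True))
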