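"""High-throughput bioactivity screens -> burst-corrected group descriptors.

Raw screens are a chemicals x assay-endpoints matrix of hit calls with AC50
potencies (µM) for actives. Potency is expressed as pAC50 = -log10(AC50/1e6)
(i.e. the negative log10 molar AC50), so larger means more potent.

Many chemicals light up broad swaths of assays at concentrations near
cytotoxicity (the "burst"). Rather than discarding such activity, each
chemical's cytotoxicity potency is subtracted out so that only activity well
above the burst scores as target-specific. The resulting score semantics:

* 0 — inactive;
* (0, 4) — activity at or near the cytotoxicity burst;
* > 4 — activity specific to the intended target.

Scores are then averaged within (biological target family, assay modality)
groups to produce one descriptor per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BioactivityMatrix",
    "filter_coverage",
    "burst_potency",
    "downweighted_score",
    "group_average",
    "bioactivity_descriptors",
    "RobustSpreadDownweight",
    "PlainDifference",
    "pac50_from_ac50_um",
]


def pac50_from_ac50_um(ac50_um):
    """pAC50 = -log10(AC50[µM] / 1e6) = 6 - log10(AC50[µM])."""
    return 6.0 - np.log10(ac50_um)


@dataclass
class BioactivityMatrix:
    """Chemicals x assay endpoints with hit calls, potencies and grouping.

    ``hit_call`` holds 1.0 (active), 0.0 (inactive) or NaN (not tested);
    ``ac50_um`` holds the AC50 in µM where active (NaN otherwise);
    ``group_map`` maps each endpoint to its (target_family, modality) bin;
    ``cytotox_endpoints`` flags the cytotoxicity/burst endpoint class.
    """

    hit_call: pd.DataFrame
    ac50_um: pd.DataFrame
    group_map: dict[str, tuple[str, str]]
    cytotox_endpoints: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.hit_call.columns) != list(self.ac50_um.columns) or list(
            self.hit_call.index
        ) != list(self.ac50_um.index):
            raise ValueError("hit_call and ac50_um must share index and columns")
        uncovered = set(self.hit_call.columns) - set(self.group_map)
        if uncovered:
            raise ValueError(f"endpoints missing from group_map: {sorted(uncovered)[:5]}")
        with np.errstate(invalid="ignore"):
            if (self.ac50_um.to_numpy() <= 0).any():
                raise ValueError("AC50 values must be > 0")

    @property
    def endpoints(self) -> pd.Index:
        return self.hit_call.columns

    @property
    def chemicals(self) -> pd.Index:
        return self.hit_call.index

    def pac50(self) -> pd.DataFrame:
        """pAC50 where active, NaN elsewhere."""
        return pac50_from_ac50_um(self.ac50_um).where(self.hit_call == 1.0)


def filter_coverage(
    matrix: BioactivityMatrix, min_endpoints: int = 800, min_chemicals: int = 500
) -> BioactivityMatrix:
    """Remove sparsely tested chemicals, then sparsely tested endpoints.

    Chemicals tested in fewer than ``min_endpoints`` endpoints are dropped
    first; endpoints then tested in fewer than ``min_chemicals`` of the
    surviving chemicals are dropped. The result satisfies both thresholds
    simultaneously (endpoint removal cannot reduce a surviving chemical's
    count below threshold on the retained columns because counts are
    re-checked iteratively until stable).
    """
    if min_endpoints < 0 or min_chemicals < 0:
        raise ValueError("coverage thresholds must be >= 0")
    hit = matrix.hit_call
    while True:
        tested = hit.notna()
        chem_ok = tested.sum(axis=1) >= min_endpoints
        hit = hit.loc[chem_ok]
        tested = hit.notna()
        ep_ok = tested.sum(axis=0) >= min_chemicals
        hit = hit.loc[:, ep_ok]
        if chem_ok.all() and ep_ok.all():
            break
        if hit.shape[0] == 0 or hit.shape[1] == 0:
            break
    ac50 = matrix.ac50_um.loc[hit.index, hit.columns]
    return replace(
        matrix,
        hit_call=hit,
        ac50_um=ac50,
        cytotox_endpoints=[e for e in matrix.cytotox_endpoints if e in set(hit.columns)],
    )


def burst_potency(matrix: BioactivityMatrix, floor: float | None = None) -> pd.Series:
    """Cytotoxicity ("burst") potency estimate per chemical.

    The median pAC50 over the chemical's active cytotoxicity-class endpoints.
    Chemicals inactive in every cytotoxicity endpoint get ``floor``; by
    default the matrix-wide minimum active potency, standing in for the
    potency at the highest tested concentration.
    """
    if not matrix.cytotox_endpoints:
        raise ValueError("no cytotoxicity endpoints flagged")
    pac = pac50_from_ac50_um(matrix.ac50_um)
    cyto = pac[matrix.cytotox_endpoints].where(matrix.hit_call[matrix.cytotox_endpoints] == 1.0)
    burst = cyto.median(axis=1)
    if floor is None:
        active_any = pac.where(matrix.hit_call == 1.0)
        floor = float(np.nanmin(active_any.to_numpy())) if active_any.notna().any().any() else 0.0
    return burst.fillna(floor)


class RobustSpreadDownweight:
    """Default burst normalization: spread-scaled difference plus offset.

    ``score = max(0, (pAC50 - burst) / scale + offset)`` for actives, 0 for
    inactives. ``scale`` defaults to the median absolute deviation of the
    burst potencies across chemicals, so one robust spread unit above the
    burst crosses the "target-specific" threshold of 4; ``offset`` = 3 puts
    at-burst activity inside (0, 4).
    """

    def __init__(self, scale: float | None = None, offset: float = 3.0):
        if scale is not None and scale <= 0:
            raise ValueError("scale must be > 0")
        self.scale = scale
        self.offset = offset

    def resolve_scale(self, burst: pd.Series) -> float:
        if self.scale is not None:
            return self.scale
        mad = float((burst - burst.median()).abs().median())
        return mad if mad > 0 else 1.0

    def __call__(self, pac50: float, burst: float, scale: float | None = None) -> float:
        s = scale if scale is not None else (self.scale if self.scale is not None else 1.0)
        return max(0.0, (pac50 - burst) / s + self.offset)


class PlainDifference:
    """Alternative normalization: plain potency difference above burst."""

    def __init__(self, offset: float = 3.0):
        self.offset = offset

    def resolve_scale(self, burst: pd.Series) -> float:
        return 1.0

    def __call__(self, pac50: float, burst: float, scale: float | None = None) -> float:
        return max(0.0, (pac50 - burst) + self.offset)


def downweighted_score(
    pac50, active, burst, strategy: RobustSpreadDownweight | None = None, scale: float | None = None
):
    """Burst-corrected activity score for one endpoint reading (vectorized).

    Inactive readings score 0; active readings score
    ``strategy(pAC50, burst)``, non-negative and monotone increasing in
    pAC50 / decreasing in burst.
    """
    strategy = strategy or RobustSpreadDownweight(scale=scale)
    pac50 = np.asarray(pac50, dtype=float)
    burst = np.asarray(burst, dtype=float)
    active = np.asarray(active)
    raw = np.vectorize(lambda p, b: strategy(p, b, scale))(pac50, burst)
    return np.where(active.astype(bool), raw, 0.0)


def score_matrix(
    matrix: BioactivityMatrix,
    strategy: RobustSpreadDownweight | None = None,
    burst: pd.Series | None = None,
) -> pd.DataFrame:
    """Chemicals x endpoints burst-corrected scores.

    Untested cells (after coverage filtering these are sporadic) are imputed
    with the endpoint's median score.
    """
    strategy = strategy or RobustSpreadDownweight()
    if burst is None:
        burst = burst_potency(matrix)
    scale = strategy.resolve_scale(burst)
    pac = pac50_from_ac50_um(matrix.ac50_um)
    diff = pac.sub(burst, axis=0) / scale if isinstance(strategy, RobustSpreadDownweight) else pac.sub(burst, axis=0)
    raw = (diff + strategy.offset).clip(lower=0.0)
    scores = raw.where(matrix.hit_call == 1.0, 0.0)
    scores = scores.where(matrix.hit_call.notna())  # keep untested as NaN
    return scores.fillna(scores.median())


def group_average(
    scores: pd.DataFrame, group_map: Mapping[str, tuple[str, str]]
) -> pd.DataFrame:
    """Average endpoint scores within (target family, modality) groups.

    Inactive (zero) scores are included in the mean, preserving the
    "0 = inactive" semantics at group level. Output columns are
    ``family_modality``, sorted; empty groups are dropped.
    """
    missing = set(scores.columns) - set(group_map)
    if missing:
        raise ValueError(f"endpoints without group: {sorted(missing)[:5]}")
    groups: dict[str, list[str]] = {}
    for ep in scores.columns:
        fam, mod = group_map[ep]
        groups.setdefault(f"{fam}_{mod}", []).append(ep)
    cols = {}
    for key in sorted(groups):
        cols[key] = scores[groups[key]].mean(axis=1)
    return pd.DataFrame(cols, index=scores.index)


def bioactivity_descriptors(
    matrix: BioactivityMatrix,
    min_endpoints: int = 800,
    min_chemicals: int = 500,
    strategy: RobustSpreadDownweight | None = None,
) -> pd.DataFrame:
    """Full raw-screen -> group-descriptor pipeline.

    Coverage filter, burst estimation, down-weighted scoring, group
    averaging. Returns the chemicals x groups descriptor table.
    """
    filtered = filter_coverage(matrix, min_endpoints, min_chemicals)
    if filtered.hit_call.shape[0] == 0 or filtered.hit_call.shape[1] == 0:
        raise ValueError("coverage filter removed everything")
    burst = burst_potency(filtered)
    scores = score_matrix(filtered, strategy=strategy, burst=burst)
    grouped = group_average(scores, filtered.group_map)
    grouped["burst_pac50"] = burst
    return grouped
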