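"""Chemical-disjoint validation design.

Because a chemical's studies are correlated (shared chemical effect),
study-level splitting leaks information across train/test; every split here
operates on chemicals, and study rows inherit their chemical's assignment.

Two pieces: a Venetian-blinds external hold-out (chemicals ordered by mean
effect level, every ``step``-th selected, giving a response-balanced 80/20
split at step 5) and repeated randomized k-fold CV over the internal
chemicals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplitPlan", "venetian_split", "chemical_kfold", "make_split_plan"]


@dataclass
class SplitPlan:
    """External/internal chemical assignment plus CV fold membership."""

    external_chemicals: set[str]
    internal_chemicals: set[str]
    folds: dict[tuple[int, int], set[str]] = field(default_factory=dict)
    k: int = 5
    repeats: int = 5
    seed: int | None = None

    def train_chemicals(self, repeat: int, fold: int) -> set[str]:
        return self.internal_chemicals - self.folds[(repeat, fold)]

    def cells(self) -> list[tuple[int, int]]:
        return sorted(self.folds)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chemical_id": c, "role": "external", "repeat": -1, "fold": -1}
            for c in sorted(self.external_chemicals)
        ]
        for (rep, fold), chems in sorted(self.folds.items()):
            rows += [
                {"chemical_id": c, "role": "internal", "repeat": rep, "fold": fold}
                for c in sorted(chems)
            ]
        return pd.DataFrame(rows)


def venetian_split(chemical_means: pd.Series, step: int = 5) -> SplitPlan:
    """Select every ``step``-th chemical (by ascending mean effect level).

    Ties in the mean are broken by chemical id (stable). The 1-based ranks
    step, 2*step, ... go external, so the external count is exactly
    floor(n / step); the response distribution of the hold-out mirrors the
    full set by construction.
    """
    if step < 2:
        raise ValueError(f"step must be >= 2, got {step}")
    if len(chemical_means) == 0:
        raise ValueError("no chemical means given")
    ranked = sorted(chemical_means.index, key=lambda c: (chemical_means[c], c))
    external = {c for i, c in enumerate(ranked, start=1) if i % step == 0}
    internal = set(ranked) - external
    return SplitPlan(external_chemicals=external, internal_chemicals=internal)


def chemical_kfold(
    internal_chemicals, k: int = 5, repeats: int = 5, seed: int = 0
) -> dict[tuple[int, int], set[str]]:
    """Randomized k-fold partitions of the internal chemicals, repeated.

    Each repeat draws a fresh permutation and cuts it into k folds whose
    sizes differ by at most one. Repeats are independent re-randomizations
    (the fold structure, not the chemical set, is resampled).
    """
    chems = sorted(internal_chemicals)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(chems):
        raise ValueError(f"k={k} exceeds number of internal chemicals ({len(chems)})")
    rng = np.random.default_rng(seed)
    folds: dict[tuple[int, int], set[str]] = {}
    for rep in range(repeats):
        perm = rng.permutation(len(chems))
        for fold, idx in enumerate(np.array_split(perm, k)):
            folds[(rep, fold)] = {chems[i] for i in idx}
    return folds


def make_split_plan(
    chemical_means: pd.Series, step: int = 5, k: int = 5, repeats: int = 5, seed: int = 0
) -> SplitPlan:
    """Venetian external split + repeated chemical-grouped k-fold CV."""
    plan = venetian_split(chemical_means, step)
    plan.folds = chemical_kfold(plan.internal_chemicals, k, repeats, seed)
    plan.k = k
    plan.repeats = repeats
    plan.seed = seed
    return plan
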