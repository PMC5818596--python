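"""Synthetic study registries and descriptor blocks with known ground truth.

The generator emulates an integrated repeat-dose toxicity dataset: ~1247
chemicals, ~4379 studies from three source databases with source-specific
mean effect levels (TOXREF 1.7, HESS 1.8, COSMOS 2.2 log10 mg/kg/day), and a
hierarchical variance decomposition of the study-level effect level

    value = source_mean + covariate_effect + chemical_effect + study_noise

with default SDs 0.40 (covariate), 0.70 (between-chemical) and 0.48
(within-chemical study noise), totalling sqrt(0.40^2+0.70^2+0.48^2) ~ 0.94.
Covariate effects are additive, category-constant offsets drawn once per run
and rescaled so their realized SD over the registry equals ``sd_covariate``.

Dose grids are 3-5 log-spaced doses (spacing factor 2, 3.16 or 10) anchored
at the latent effect level, with doses above the anchor capped at the
guideline limit (10^3 mg/kg/day for most studies, 10^4 for a limit-dose
minority). A configurable fraction of grids (10% by default) deliberately
miss the latent effect and become censored observations: half NEL at the
highest tested dose (capped at the guideline limit), half LEL at the lowest
tested dose. Censoring is independent of the latent level by design, so the
observed effect-level distribution keeps the configured moments.

Because every latent quantity is returned as ground truth, parameter
recovery (variance components, baseline/benchmark explained-variance
bounds) is directly testable downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bioactivity import BioactivityMatrix
from .descriptors import DescriptorMatrix
from .study import StudyRecord, DEFAULT_PPM_FACTORS

__all__ = [
    "GeneratorConfig",
    "BlockSpec",
    "ConfigurationError",
    "generate_registry",
    "generate_descriptors",
    "write_ground_truth",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


# Joint (study type, species) design frequencies patterned on the combined
# study counts of the three source databases.
DEFAULT_DESIGN_FREQUENCY: dict[tuple[str, str], float] = {
    ("SUB", "rat"): 774,
    ("CHR", "rat"): 566,
    ("DEV", "rat"): 542,
    ("CHR", "mouse"): 477,
    ("DEV", "rabbit"): 395,
    ("SAC", "rat"): 369,
    ("MGR", "rat"): 368,
    ("CHR", "dog"): 307,
    ("SUB", "mouse"): 263,
    ("SUB", "dog"): 200,
    ("DEV", "mouse"): 36,
    ("SAC", "mouse"): 33,
    ("SAC", "dog"): 31,
    ("MGR", "mouse"): 18,
}

DEFAULT_STRAIN_GROUPS: dict[str, dict[str, float]] = {
    "rat": {"sprague_dawley": 0.35, "wistar": 0.30, "f344": 0.20, "other_rat": 0.15},
    "mouse": {"cd1": 0.40, "b6c3f1": 0.35, "other_mouse": 0.25},
    "dog": {"beagle": 0.90, "other_dog": 0.10},
    "rabbit": {"new_zealand_white": 0.80, "other_rabbit": 0.20},
}

DEFAULT_ADMIN_FREQUENCY: dict[str, float] = {
    "food": 0.45,
    "gavage": 0.35,
    "water": 0.15,
    "capsule": 0.05,
}


@dataclass
class BlockSpec:
    """Shape and signal content of one synthetic descriptor block."""

    n_features: int
    signal_fraction: float
    kind: str = "continuous"  # continuous | binary | bioactivity
    missing_rate: float = 0.0
    n_duplicate_pairs: int = 0  # planted exact-copy column pairs (|r| = 1)
    n_correlated_pairs: int = 0  # planted |r| ~ 0.95 pairs
    n_near_constant: int = 0  # planted constant / near-constant columns
    availability: float = 1.0  # fraction of chemicals possessing the block


def _default_blocks() -> dict[str, BlockSpec]:
    return {
        "physchem": BlockSpec(12, 0.5, missing_rate=0.02, n_duplicate_pairs=1),
        "padel": BlockSpec(
            60, 0.2, missing_rate=0.05, n_duplicate_pairs=2, n_correlated_pairs=2, n_near_constant=2
        ),
        "toxprint": BlockSpec(40, 0.15, kind="binary", n_duplicate_pairs=1, n_near_constant=2),
        "toxcast": BlockSpec(1000, 0.15, kind="bioactivity", availability=603 / 1247),
        "httk": BlockSpec(10, 0.3, missing_rate=0.10, availability=391 / 1247),
    }


@dataclass
class GeneratorConfig:
    """All tunables of the synthetic study-and-descriptor generator."""

    n_chemicals: int = 1247
    studies_per_source: dict[str, int] = field(
        default_factory=lambda: {"TOXREF": 3752, "HESS": 432, "COSMOS": 195}
    )
    source_means: dict[str, float] = field(
        default_factory=lambda: {"TOXREF": 1.7, "HESS": 1.8, "COSMOS": 2.2}
    )
    #: relative weights for allocating chemicals to sources (per-source
    #: chemical counts of the emulated integration: 836/411/141)
    chemical_share: dict[str, float] = field(
        default_factory=lambda: {"TOXREF": 836, "HESS": 411, "COSMOS": 141}
    )
    sd_covariate: float = 0.40
    sd_chemical: float = 0.70
    sd_study: float = 0.48
    design_frequency: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_DESIGN_FREQUENCY)
    )
    strain_groups: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(w) for s, w in DEFAULT_STRAIN_GROUPS.items()}
    )
    admin_frequency: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADMIN_FREQUENCY)
    )
    #: relative variance share of each covariate in the total covariate
    #: effect (the total SD is sd_covariate); weighted toward the
    #: well-populated, low-cardinality covariates so the configured
    #: covariate variance is recoverable by a study-level model rather
    #: than dispersed over rare strain categories
    covariate_share: dict[str, float] = field(
        default_factory=lambda: {
            "study_type": 0.20,
            "species": 0.15,
            "strain_group": 0.15,
            "admin_method": 0.10,
            "dose_no": 0.15,
            "dose_spacing": 0.25,
        }
    )
    #: fraction of dose grids designed to bracket the latent effect; the
    #: remainder are deliberately censored (half NEL, half LEL-at-lowest)
    frac_in_range: float = 0.90
    #: guideline top-dose cap, log10 mg/kg/day, and the fraction of studies
    #: allowed a higher (limit-dose) cap
    top_dose_cap: float = 3.0
    high_cap: float = 4.0
    high_cap_fraction: float = 0.15
    loael_fraction: float = 0.30  # effect-bearing studies given a reviewed LOAEL
    ppm_fraction: float = 0.20  # feed studies reported in ppm
    neuro_fraction: float = 0.02  # studies with a neurotoxicity-only finding
    descriptor_block_specs: dict[str, BlockSpec] = field(default_factory=_default_blocks)
    seed: int = 0

    def validate(self) -> None:
        for name in ("sd_covariate", "sd_chemical", "sd_study"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_chemicals < 2:
            raise ConfigurationError("n_chemicals must be >= 2")
        for fname in ("frac_in_range", "high_cap_fraction", "loael_fraction", "ppm_fraction", "neuro_fraction"):
            v = getattr(self, fname)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{fname} must be in [0, 1]")
        if set(self.studies_per_source) != set(self.source_means):
            raise ConfigurationError("studies_per_source and source_means must share sources")
        if any(w < 0 for w in self.covariate_share.values()) or sum(self.covariate_share.values()) <= 0:
            raise ConfigurationError("covariate_share weights must be non-negative and sum > 0")
        for table_name in ("design_frequency", "admin_frequency", "chemical_share"):
            table = getattr(self, table_name)
            if not table or any(w < 0 for w in table.values()) or sum(table.values()) <= 0:
                raise ConfigurationError(f"{table_name} weights must be non-negative and sum > 0")
        for sp, table in self.strain_groups.items():
            if not table or sum(table.values()) <= 0:
                raise ConfigurationError(f"strain_groups[{sp}] weights must sum > 0")
        total_chem = self._chemicals_per_source()
        for src, n in self.studies_per_source.items():
            if n < total_chem[src]:
                raise ConfigurationError(
                    f"studies_per_source[{src}]={n} is fewer than its {total_chem[src]} chemicals"
                )

    def _chemicals_per_source(self) -> dict[str, int]:
        """Largest-remainder allocation of chemicals to sources."""
        sources = sorted(self.studies_per_source)
        weights = np.array([self.chemical_share.get(s, 1.0) for s in sources], dtype=float)
        weights /= weights.sum()
        raw = weights * self.n_chemicals
        counts = np.floor(raw).astype(int)
        # at least one chemical per source with studies
        counts = np.maximum(counts, 1)
        rema = raw - np.floor(raw)
        while counts.sum() < self.n_chemicals:
            i = int(np.argmax(rema))
            counts[i] += 1
            rema[i] = -1
        while counts.sum() > self.n_chemicals:
            i = int(np.argmin(rema))
            counts[i] -= 1
            rema[i] = 2
        return dict(zip(sources, (int(c) for c in counts)))


def _choice(rng, items, weights):
    w = np.asarray(weights, dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())]


def _covariate_offsets(rng, categories_per_covariate: dict[str, list[str]]):
    return {
        cov: {cat: rng.normal() for cat in cats}
        for cov, cats in categories_per_covariate.items()
    }


def generate_registry(
    config: GeneratorConfig,
) -> tuple[list[StudyRecord], dict[str, float]]:
    """Generate a study registry plus ground-truth chemical effects.

    Returns the list of study records (all of which satisfy the inclusion
    filters apart from deliberately planted neurotoxicity-only findings,
    which the filter step is expected to neutralize) and the map from
    chemical id to its latent chemical random effect.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_chem, r_design, r_offsets, r_noise, r_dose = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    sources = sorted(config.studies_per_source)
    chems_per_source = config._chemicals_per_source()

    chemicals: list[str] = []
    chem_source: dict[str, str] = {}
    for src in sources:
        for _ in range(chems_per_source[src]):
            cid = f"C{len(chemicals):05d}"
            chemicals.append(cid)
            chem_source[cid] = src
    chem_effect = {c: r_chem.normal(0.0, config.sd_chemical) for c in chemicals}

    # studies per chemical: one guaranteed, remainder multinomial within source
    study_chem: list[str] = []
    for src in sources:
        src_chems = [c for c in chemicals if chem_source[c] == src]
        n_studies = config.studies_per_source[src]
        study_chem.extend(src_chems)
        extra = n_studies - len(src_chems)
        counts = r_chem.multinomial(extra, np.full(len(src_chems), 1.0 / len(src_chems)))
        for c, k in zip(src_chems, counts):
            study_chem.extend([c] * int(k))

    n = len(study_chem)

    # categorical design draws
    design_items = sorted(config.design_frequency)
    design_w = [config.design_frequency[k] for k in design_items]
    designs = [_choice(r_design, design_items, design_w) for _ in range(n)]
    study_types = [d[0] for d in designs]
    species = [d[1] for d in designs]
    strains = []
    for sp in species:
        table = config.strain_groups.get(sp, {f"other_{sp}": 1.0})
        strains.append(_choice(r_design, sorted(table), [table[k] for k in sorted(table)]))
    admin_items = sorted(config.admin_frequency)
    admin_w = [config.admin_frequency[k] for k in admin_items]
    admins = [_choice(r_design, admin_items, admin_w) for _ in range(n)]

    # dose-grid design (count + spacing) is itself a study covariate and
    # carries its own category effect, so it is drawn before the latents
    spacing_steps = [math.log10(2.0), math.log10(3.16), 1.0]
    dose_counts = [int(_choice(r_design, [3, 4, 5], [0.5, 0.3, 0.2])) for _ in range(n)]
    step_choices = [spacing_steps[int(r_design.integers(3))] for _ in range(n)]

    # per-category covariate offsets, centered, each covariate scaled to its
    # configured variance share, the sum rescaled to sd_covariate
    cov_values = {
        "study_type": study_types,
        "species": species,
        "strain_group": strains,
        "admin_method": admins,
        "dose_no": [str(c) for c in dose_counts],
        "dose_spacing": [f"{s:.3f}" for s in step_choices],
    }
    offsets = _covariate_offsets(
        r_offsets, {cov: sorted(set(vals)) for cov, vals in cov_values.items()}
    )
    raw = np.zeros(n)
    for cov, vals in cov_values.items():
        contrib = np.array([offsets[cov][v] for v in vals])
        contrib = contrib - contrib.mean()
        sd = contrib.std()
        share = config.covariate_share.get(cov, 1.0)
        if sd > 0:
            contrib = contrib / sd * math.sqrt(max(share, 0.0))
        raw += contrib
    raw_sd = raw.std()
    if config.sd_covariate > 0 and raw_sd > 0:
        cov_effect = raw * (config.sd_covariate / raw_sd)
    else:
        cov_effect = np.zeros(n)

    noise = r_noise.normal(0.0, config.sd_study, size=n) if config.sd_study > 0 else np.zeros(n)

    records: list[StudyRecord] = []
    for i, cid in enumerate(study_chem):
        src = chem_source[cid]
        latent = config.source_means[src] + cov_effect[i] + chem_effect[cid] + noise[i]

        n_doses = dose_counts[i]
        step = step_choices[i]
        cap = config.high_cap if r_dose.random() < config.high_cap_fraction else config.top_dose_cap

        u = r_dose.random()
        if u < config.frac_in_range:
            # grid anchored at the latent effect; >=1 clean dose below the
            # anchor, doses above it only up to the guideline cap
            pos = 1 + int(r_dose.integers(n_doses - 1))
            room = int(math.floor((cap - latent) / step + 1e-9))
            top = latent + min(n_doses - 1 - pos, max(0, room)) * step
        elif u < config.frac_in_range + (1 - config.frac_in_range) / 2:
            # censored NEL: the whole grid sits below the latent effect
            top = min(latent - (0.25 + 0.75 * r_dose.random()) * step, cap)
        else:
            # censored LEL: effect already at the lowest tested dose
            lowest = latent + (0.25 + 0.75 * r_dose.random()) * step
            top = lowest + (n_doses - 1) * step
            if top > cap:
                top = max(cap, lowest)

        doses_log = [top - (n_doses - 1 - k) * step for k in range(n_doses)]
        effects = [d >= latent - 1e-9 for d in doses_log]

        # units: a fraction of feed studies report doses in ppm
        unit = "mg/kg/day"
        factor = 1.0
        if admins[i] == "food" and r_dose.random() < config.ppm_fraction:
            unit = "ppm"
            factor = DEFAULT_PPM_FACTORS[(species[i], study_types[i])]
        dose_levels = [(10.0**d / factor, unit) for d in doses_log]

        loael = None
        if any(effects) and r_dose.random() < config.loael_fraction:
            loael = (10.0**latent if latent >= doses_log[0] - 1e-9 else 10.0 ** doses_log[0], "mg/kg/day")

        neuro = [False] * n_doses
        if config.neuro_fraction > 0 and r_dose.random() < config.neuro_fraction:
            clean = [k for k, e in enumerate(effects) if not e]
            if clean:
                k = clean[-1]
                effects[k] = True
                neuro[k] = True

        purity = None if r_dose.random() < 0.10 else float(np.clip(r_dose.normal(97.0, 2.0), 85, 100))
        year = None if r_dose.random() < 0.15 else int(r_dose.integers(1975, 2016))

        records.append(
            StudyRecord(
                study_id=f"S{i:05d}",
                chemical_id=cid,
                source=src,
                study_type=study_types[i],
                species=species[i],
                strain_group=strains[i],
                admin_method=admins[i],
                dose_levels=dose_levels,
                effects=effects,
                neuro_only=neuro,
                loael=loael,
                guideline_ok=True,
                purity=purity,
                study_year=year,
            )
        )
    return records, chem_effect


# ---------------------------------------------------------------------------
# descriptor blocks


def _continuous_block(rng, name, spec, chems, z):
    n, p = len(chems), spec.n_features
    n_signal = int(round(spec.signal_fraction * p))
    X = np.empty((n, p))
    for j in range(p):
        if j < n_signal:
            rho = rng.uniform(0.35, 0.6) * rng.choice([-1.0, 1.0])
            X[:, j] = rho * z + math.sqrt(1 - rho**2) * rng.normal(size=n)
        else:
            X[:, j] = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2.0), size=n)
    cols = [f"{name}_{j:03d}" for j in range(p)]
    return X, cols


def _binary_block(rng, name, spec, chems, z):
    n, p = len(chems), spec.n_features
    n_signal = int(round(spec.signal_fraction * p))
    X = np.empty((n, p))
    for j in range(p):
        base = rng.uniform(0.10, 0.50)
        logit = math.log(base / (1 - base))
        if j < n_signal:
            a = rng.uniform(0.5, 1.2) * rng.choice([-1.0, 1.0])
            prob = 1.0 / (1.0 + np.exp(-(logit + a * z)))
        else:
            prob = np.full(n, base)
        X[:, j] = (rng.random(n) < prob).astype(float)
    cols = [f"{name}_{j:03d}" for j in range(p)]
    return X, cols


def _plant_structure(rng, X, cols, name, spec):
    """Append duplicated, highly-correlated and near-constant columns."""
    n = X.shape[0]
    extra, extra_cols = [], []
    for d in range(spec.n_duplicate_pairs):
        j = int(rng.integers(X.shape[1]))
        extra.append(X[:, j].copy())
        extra_cols.append(f"{name}_dup{d:02d}")
    for d in range(spec.n_correlated_pairs):
        j = int(rng.integers(X.shape[1]))
        extra.append(X[:, j] + 0.2 * np.std(X[:, j]) * rng.normal(size=n))
        extra_cols.append(f"{name}_cor{d:02d}")
    for d in range(spec.n_near_constant):
        col = np.zeros(n)
        if d % 2 == 1 and n > 2:  # near- (not exactly) constant
            col[rng.choice(n, size=max(1, n // 200), replace=False)] = 1.0
        extra.append(col)
        extra_cols.append(f"{name}_const{d:02d}")
    if extra:
        X = np.column_stack([X] + extra)
        cols = cols + extra_cols
    return X, cols


def _bioactivity_block(rng, spec, chems, z) -> BioactivityMatrix:
    """Synthetic screen: hit calls + AC50s with an embedded cytotox burst.

    31 target families (one of them cytotoxicity) x 2 modalities = 62 assay
    groups. More toxic chemicals (lower effect level, i.e. negative z) are
    active in more signal endpoints and at higher specific potency.
    """
    n, p = len(chems), spec.n_features
    families = ["cytotoxicity"] + [f"family_{i:02d}" for i in range(1, 31)]
    modalities = ["agonist", "antagonist"]
    group_keys = [(f, m) for f in families for m in modalities]
    # endpoints per group: cytotoxicity groups get extra weight
    weights = np.array([3.0 if f == "cytotoxicity" else 1.0 for f, _ in group_keys])
    counts = np.maximum(1, rng.multinomial(p - len(group_keys), weights / weights.sum()) + 1)
    endpoints, group_map, cytotox = [], {}, []
    for (fam, mod), c in zip(group_keys, counts):
        for e in range(int(c)):
            ep = f"ep_{fam}_{mod}_{e:03d}"
            endpoints.append(ep)
            group_map[ep] = (fam, mod)
            if fam == "cytotoxicity":
                cytotox.append(ep)
    p = len(endpoints)

    tox = -z  # toxicity: high = low effect level
    burst = np.clip(rng.normal(4.5, 0.5, size=n), 3.5, None)

    # tested mask with planted sparse rows/columns for the coverage filter
    tested = rng.random((n, p)) < 0.95
    sparse_chems = rng.random(n) < 0.03
    tested[sparse_chems] = rng.random((int(sparse_chems.sum()), p)) < 0.40
    sparse_eps = rng.random(p) < 0.03
    tested[:, sparse_eps] = (rng.random((n, int(sparse_eps.sum()))) < 0.40) & tested[:, sparse_eps]

    n_noncyto = p - len(cytotox)
    n_signal = int(round(spec.signal_fraction * n_noncyto))
    noncyto_idx = [j for j, ep in enumerate(endpoints) if ep not in set(cytotox)]
    signal_idx = set(noncyto_idx[:n_signal])

    hit = np.zeros((n, p))
    pac = np.full((n, p), np.nan)
    for j, ep in enumerate(endpoints):
        if ep in set(cytotox):
            prob = np.full(n, 0.80)
            pot = burst + rng.normal(0, 0.15, size=n)
        elif j in signal_idx:
            base = rng.uniform(0.05, 0.25)
            slope = rng.uniform(0.15, 0.35)
            prob = np.clip(base + slope * tox, 0.01, 0.95)
            pot = burst + np.clip(rng.uniform(0.5, 2.5, size=n) + 0.5 * tox, 0.0, None)
        else:
            prob = np.full(n, rng.uniform(0.03, 0.20))
            pot = burst + np.abs(rng.normal(0, 0.2, size=n))
        active = rng.random(n) < prob
        hit[:, j] = active.astype(float)
        pac[active, j] = pot[active]
    hit_df = pd.DataFrame(hit, index=chems, columns=endpoints).where(tested)
    ac50 = pd.DataFrame(10.0 ** (6.0 - pac), index=chems, columns=endpoints).where(
        tested & (hit == 1.0)
    )
    return BioactivityMatrix(hit_call=hit_df, ac50_um=ac50, group_map=group_map, cytotox_endpoints=cytotox)


def generate_descriptors(
    chemicals: list[str],
    true_effects: Mapping[str, float],
    config: GeneratorConfig,
) -> dict[str, DescriptorMatrix | BioactivityMatrix]:
    """Generate every configured descriptor block.

    Continuous/binary blocks carry ``signal_fraction`` features correlated
    with the chemical's latent effect; the bioactivity block is returned raw
    (hit calls + AC50s) for the bioactivity pipeline to process. Block
    availability is nested (chemicals with the rarest block also have all
    commoner ones), emulating sequential descriptor-set coverage.
    """
    if not chemicals:
        raise ConfigurationError("chemicals must be non-empty")
    known_kinds = {"continuous", "binary", "bioactivity"}
    for name, spec in config.descriptor_block_specs.items():
        if spec.kind not in known_kinds:
            raise ConfigurationError(f"descriptor_block_specs[{name}].kind unknown: {spec.kind}")
        if not 0 <= spec.signal_fraction <= 1:
            raise ConfigurationError(f"descriptor_block_specs[{name}].signal_fraction must be in [0, 1]")
        if not 0 <= spec.missing_rate < 1:
            raise ConfigurationError(f"descriptor_block_specs[{name}].missing_rate must be in [0, 1)")

    ss = np.random.SeedSequence([config.seed, 1])
    rngs = {name: np.random.default_rng(s) for name, s in
            zip(sorted(config.descriptor_block_specs), ss.spawn(len(config.descriptor_block_specs) + 1))}
    r_avail = np.random.default_rng(ss.spawn(1)[0])

    effects = np.array([true_effects[c] for c in chemicals])
    sd = effects.std()
    z = (effects - effects.mean()) / sd if sd > 0 else np.zeros(len(effects))
    z_of = dict(zip(chemicals, z))

    # nested availability: one permutation, prefix per block
    perm = list(np.array(chemicals)[r_avail.permutation(len(chemicals))])
    blocks: dict[str, DescriptorMatrix | BioactivityMatrix] = {}
    for name in sorted(config.descriptor_block_specs):
        spec = config.descriptor_block_specs[name]
        rng = rngs[name]
        avail = sorted(perm[: max(2, int(round(spec.availability * len(chemicals))))])
        zz = np.array([z_of[c] for c in avail])
        if spec.kind == "bioactivity":
            blocks[name] = _bioactivity_block(rng, spec, avail, zz)
            continue
        if spec.kind == "continuous":
            X, cols = _continuous_block(rng, name, spec, avail, zz)
        else:
            X, cols = _binary_block(rng, name, spec, avail, zz)
        X, cols = _plant_structure(rng, X, cols, name, spec)
        if spec.missing_rate > 0:
            mask = rng.random(X.shape) < spec.missing_rate
            X = np.where(mask, np.nan, X)
        df = pd.DataFrame(X, index=avail, columns=cols)
        blocks[name] = DescriptorMatrix(df, pd.Series(name, index=cols))
    return blocks


def write_ground_truth(chem_effect: Mapping[str, float], path) -> None:
    """Ground-truth chemical effects as delimited text (never read back)."""
    pd.Series(chem_effect, name="true_chemical_effect").rename_axis("chemical_id").to_csv(
        path, sep="\t"
    )
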