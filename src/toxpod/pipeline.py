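"""End-to-end pipeline stages with file artifacts and a run manifest.

Each stage reads the previous stage's delimited-text artifacts from the run
directory, so a run is resumable and every artifact is reproducible from
the manifest (config hash + root seed). All randomness flows from the root
seed; per-stage seeds are derived, never drawn.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioactivity as bio
from . import descriptors as desc
from . import forward as fwd
from . import model as mdl
from . import splitting as spl
from . import study as stu
from . import synthetic as syn
from .evaluation import CVResult, EvalReport, chemical_level_eval, evaluate_external, run_cv, r2_dotplot, pred_obs_scatter

__all__ = ["RunConfig", "Pipeline", "ConfigurationError"]

ConfigurationError = syn.ConfigurationError


@dataclass
class RunConfig:
    """All pipeline tunables; defaults follow the standard workflow."""

    outdir: str = "toxpod_run"
    seed: int = 0
    # generator scale overrides (None -> generator defaults)
    n_chemicals: int | None = None
    studies_per_source: dict[str, int] | None = None
    # descriptor preparation
    freq_cut: float = 95 / 5
    corr_cutoff: float = 0.9
    # bioactivity coverage
    min_endpoints: int = 800
    min_chemicals: int = 500
    # splitting
    step: int = 5
    k: int = 5
    repeats: int = 5
    # modeling
    ntree_cv: int = 250
    ntree_final: int = 2500
    tiers: tuple[str, ...] = ("baseline", "chem", "chem_bio", "chem_bio_kin", "benchmark")
    # forward prediction
    n_mock: int = 5
    truncation: tuple[float, float] = (-2.0, 4.0)

    def validate(self) -> None:
        if not 0 < self.corr_cutoff <= 1:
            raise ConfigurationError(f"corr_cutoff must be in (0, 1], got {self.corr_cutoff}")
        if self.k < 2 or self.repeats < 1 or self.step < 2 or self.n_mock < 1:
            raise ConfigurationError("k >= 2, repeats >= 1, step >= 2, n_mock >= 1 required")
        if self.ntree_cv < 1 or self.ntree_final < 1:
            raise ConfigurationError("tree counts must be >= 1")
        unknown = set(self.tiers) - set(mdl.TIERS)
        if unknown:
            raise ConfigurationError(f"unknown tiers: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class Pipeline:
    """Stage runner over a single output directory."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- manifest -----------------------------------------------------------
    def _log_stage(self, stage: str, **info) -> None:
        path = self.out / "manifest.json"
        manifest = json.loads(path.read_text()) if path.exists() else {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "stages": {},
        }
        manifest["stages"][stage] = {k: v for k, v in sorted(info.items())}
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        cfg = syn.GeneratorConfig(seed=self.config.seed)
        if self.config.n_chemicals is not None:
            cfg.n_chemicals = self.config.n_chemicals
        if self.config.studies_per_source is not None:
            cfg.studies_per_source = dict(self.config.studies_per_source)
        records, truth = syn.generate_registry(cfg)
        stu.write_registry(records, self.out / "registry.tsv")
        syn.write_ground_truth(truth, self.out / "ground_truth.tsv")
        blocks = syn.generate_descriptors([r for r in sorted(truth)], truth, cfg)
        block_manifest = {}
        for name, block in blocks.items():
            if isinstance(block, bio.BioactivityMatrix):
                block.hit_call.to_csv(self.out / f"{name}_hits.tsv", sep="\t")
                block.ac50_um.to_csv(self.out / f"{name}_ac50.tsv", sep="\t")
                gm = pd.DataFrame(
                    [
                        {"endpoint": e, "target_family": f, "modality": m,
                         "cytotox": int(e in set(block.cytotox_endpoints))}
                        for e, (f, m) in block.group_map.items()
                    ]
                )
                gm.to_csv(self.out / f"{name}_groups.tsv", sep="\t", index=False)
                block_manifest[name] = {"kind": "bioactivity"}
            else:
                block.to_files(self.out / f"block_{name}.tsv", self.out / f"block_{name}_cols.tsv")
                block_manifest[name] = {"kind": "matrix"}
        (self.out / "blocks.json").write_text(json.dumps(block_manifest, indent=2, sort_keys=True))
        self._log_stage("simulate", n_studies=len(records), n_chemicals=len(truth))

    def _load_blocks(self) -> dict:
        manifest = json.loads((self.out / "blocks.json").read_text())
        blocks = {}
        for name, meta in manifest.items():
            if meta["kind"] == "bioactivity":
                hits = pd.read_csv(self.out / f"{name}_hits.tsv", sep="\t", index_col=0)
                ac50 = pd.read_csv(self.out / f"{name}_ac50.tsv", sep="\t", index_col=0)
                gm = pd.read_csv(self.out / f"{name}_groups.tsv", sep="\t")
                group_map = {r.endpoint: (r.target_family, r.modality) for r in gm.itertuples()}
                cytotox = list(gm.loc[gm.cytotox == 1, "endpoint"])
                blocks[name] = bio.BioactivityMatrix(hits, ac50, group_map, cytotox)
            else:
                blocks[name] = desc.DescriptorMatrix.from_files(
                    self.out / f"block_{name}.tsv", self.out / f"block_{name}_cols.tsv"
                )
        return blocks

    def prepare(self) -> None:
        required = ["registry.tsv", "blocks.json"]
        for f in required:
            if not (self.out / f).exists():
                raise FileNotFoundError(self.out / f)
        records = stu.read_registry(self.out / "registry.tsv")
        kept = stu.filter_studies(records)
        effects = stu.effect_table(kept)
        effects.to_csv(self.out / "effect_levels.tsv", sep="\t", index=False)

        blocks = self._load_blocks()
        matrix_blocks = {}
        for name, block in blocks.items():
            if isinstance(block, bio.BioactivityMatrix):
                grouped = bio.bioactivity_descriptors(
                    block, self.config.min_endpoints, self.config.min_chemicals
                )
                grouped.columns = [f"{name}_{c}" for c in grouped.columns]
                matrix_blocks[name] = desc.DescriptorMatrix(
                    grouped, pd.Series(name, index=grouped.columns)
                )
            else:
                matrix_blocks[name] = block
        availability = {n: sorted(mdl.block_availability({n: b})[n]) for n, b in matrix_blocks.items()}
        prepared, report = desc.prepare_descriptors(
            matrix_blocks, self.config.freq_cut, self.config.corr_cutoff
        )
        prepared.to_files(self.out / "descriptors.tsv", self.out / "descriptors_cols.tsv")
        report.to_frame().to_csv(self.out / "descriptors_removed.tsv", sep="\t", index=False)
        (self.out / "availability.json").write_text(json.dumps(availability, indent=2, sort_keys=True))
        self._log_stage(
            "prepare",
            n_studies_kept=len(kept),
            n_descriptors_in=report.n_input,
            n_descriptors_out=report.n_output,
        )

    def _load_prepared(self):
        effects = pd.read_csv(self.out / "effect_levels.tsv", sep="\t")
        prepared = desc.DescriptorMatrix.from_files(
            self.out / "descriptors.tsv", self.out / "descriptors_cols.tsv"
        )
        availability = {
            k: set(v) for k, v in json.loads((self.out / "availability.json").read_text()).items()
        }
        return effects, prepared, availability

    def split(self) -> None:
        effects, _, _ = self._load_prepared()
        means = stu.chemical_mean_effect(effects)
        plan = spl.make_split_plan(
            means, self.config.step, self.config.k, self.config.repeats, self.config.seed
        )
        plan.to_frame().to_csv(self.out / "split.tsv", sep="\t", index=False)
        self._log_stage(
            "split",
            n_external=len(plan.external_chemicals),
            n_internal=len(plan.internal_chemicals),
        )

    def _load_plan(self) -> spl.SplitPlan:
        df = pd.read_csv(self.out / "split.tsv", sep="\t")
        external = set(df.loc[df.role == "external", "chemical_id"])
        internal = set(df.loc[df.role == "internal", "chemical_id"].unique())
        folds: dict[tuple[int, int], set[str]] = {}
        for row in df[df.role == "internal"].itertuples():
            folds.setdefault((int(row.repeat), int(row.fold)), set()).add(row.chemical_id)
        return spl.SplitPlan(
            external_chemicals=external,
            internal_chemicals=internal,
            folds=folds,
            k=self.config.k,
            repeats=self.config.repeats,
            seed=self.config.seed,
        )

    def _tables(self) -> dict[str, mdl.ModelingTable]:
        effects, prepared, availability = self._load_prepared()
        tables = {}
        for tier in self.config.tiers:
            tables[tier] = mdl.assemble_table(
                effects, tier, descriptors=prepared, availability=availability
            )
        return tables

    def train(self) -> dict[str, CVResult]:
        plan = self._load_plan()
        tables = self._tables()
        cv_results: dict[str, CVResult] = {}
        scores = []
        for tier, table in tables.items():
            cv = run_cv(table, plan, ntree=self.config.ntree_cv, seed=self.config.seed)
            cv_results[tier] = cv
            s = cv.scores.assign(tier=tier)
            scores.append(s)
            # final model: full internal data, mean CV bias coefficients
            internal = table.subset_chemicals(plan.internal_chemicals)
            final = mdl.EffectLevelForest(internal).fit(
                ntree=self.config.ntree_final, seed=self.config.seed
            )
            final.set_bias(*cv.mean_bias())
            final.save(self.out / f"model_{tier}.joblib", self.out / f"model_{tier}.json")
            final.importance.to_csv(self.out / f"importance_{tier}.tsv", sep="\t", index=False)
        pd.concat(scores, ignore_index=True).to_csv(self.out / "cv_scores.tsv", sep="\t", index=False)
        self._log_stage("train", tiers=list(tables), ntree_cv=self.config.ntree_cv)
        return cv_results

    def _load_fit(self, tier: str, table, plan) -> mdl.ForestResults:
        import joblib

        forest = joblib.load(self.out / f"model_{tier}.joblib")
        meta = json.loads((self.out / f"model_{tier}.json").read_text())
        internal = table.subset_chemicals(plan.internal_chemicals)
        return mdl.ForestResults(
            model=mdl.EffectLevelForest(internal),
            forest=forest,
            tier=tier,
            ntree=meta["ntree"],
            mtry=meta["mtry"],
            bias_slope=meta["bias_slope"],
            bias_intercept=meta["bias_intercept"],
            importance=pd.read_csv(self.out / f"importance_{tier}.tsv", sep="\t"),
            seed=meta["seed"],
            target_maps={
                col: {int(k): v for k, v in mapping.items()}
                for col, mapping in meta.get("target_maps", {}).items()
            },
            train_mean=meta.get("train_mean", float("nan")),
        )

    def evaluate(self) -> dict:
        plan = self._load_plan()
        tables = self._tables()
        cv_scores = pd.read_csv(self.out / "cv_scores.tsv", sep="\t")
        metrics: dict = {"cv_median_r2": {}, "external": {}}
        cv_results = {}
        for tier, table in tables.items():
            tier_scores = cv_scores[cv_scores.tier == tier]
            metrics["cv_median_r2"][tier] = float(tier_scores["r2"].median())
            cv_results[tier] = CVResult(tier=tier, scores=tier_scores, predictions=pd.DataFrame())
            res = self._load_fit(tier, table, plan)
            study_rep = evaluate_external(res, table, plan)
            chem_rep = chemical_level_eval(study_rep)
            metrics["external"][tier] = {
                "study": {"r2": study_rep.r2, "rmse": study_rep.rmse, "n": study_rep.n,
                          "fraction_within_1log": study_rep.fraction_within_1log},
                "chemical": {"r2": chem_rep.r2, "rmse": chem_rep.rmse, "n": chem_rep.n,
                             "fraction_within_1log": chem_rep.fraction_within_1log},
            }
            study_rep.frame.to_csv(self.out / f"external_{tier}.tsv", sep="\t", index=False)
            pred_obs_scatter(study_rep, self.out / f"external_{tier}.png")
        r2_dotplot(cv_results, self.out / "cv_r2_dotplot.png")
        (self.out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
        self._log_stage("evaluate", tiers=list(tables))
        return metrics

    def predict(self) -> pd.DataFrame:
        effects, prepared, availability = self._load_prepared()
        metrics = json.loads((self.out / "metrics.json").read_text())
        pool = fwd.observed_covariate_pool(effects)
        # deployable tiers, richest first (benchmark needs in vivo data, skip)
        deploy = [t for t in ("chem_bio_kin", "chem_bio", "chem") if t in self.config.tiers]
        if not deploy:
            deploy = ["baseline"]
        plan = self._load_plan()
        tables = self._tables()
        assigned: set[str] = set()
        chemical_blocks: dict[str, list[str]] = {}
        all_chems = set(prepared.chemicals)
        for tier in deploy:
            have = set.intersection(*(availability[b] for b in mdl.TIER_BLOCKS[tier])) if mdl.TIER_BLOCKS[tier] else all_chems
            chemical_blocks[tier] = sorted(have - assigned)
            assigned |= have
        fits = {}
        rmse_by_tier = {}
        for tier in deploy:
            fits[tier] = self._load_fit(tier, tables[tier], plan)
            rmse_by_tier[tier] = metrics["external"].get(tier, {}).get("study", {}).get("rmse", float("nan"))
        results = fwd.forward_predict_cascade(
            chemical_blocks,
            prepared.data,
            fits,
            pool,
            n_mock=self.config.n_mock,
            seed=self.config.seed,
            external_rmse=rmse_by_tier,
        )
        table = fwd.results_table(results)
        table.to_csv(self.out / "forward_predictions.tsv", sep="\t", index=False)
        self._log_stage("predict", n_chemicals=len(table), n_mock=self.config.n_mock)
        return table

    def run_all(self) -> None:
        self.simulate()
        self.prepare()
        self.split()
        self.train()
        self.evaluate()
        self.predict()
        self._log_stage("all", stages=6)
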