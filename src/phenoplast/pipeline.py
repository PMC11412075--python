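"""End-to-end orchestration: simulate -> derive -> indices -> stomatal fit ->
recovery ANOVA -> multivariate, driven by one YAML config and fully seeded.

Every run writes a deterministic ``manifest.json`` (configuration echo, seeds
and SHA-256 digests of inputs and outputs); two runs with identical seeds are
byte-identical, so the manifest suffices to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .groupstats import anova_by_trait
from .multivariate import build_family_features, cluster_families, correlation_matrix, pca_families
from .rdpi import build_index_matrix, family_difference_test
from .simulate import ExperimentDesign, default_profiles, profiles_from_yaml, simulate
from .stomatal import coefficient_report, fit_loglinear, sequential_anova
from .traits import GAS_EXCHANGE_TRAITS, TraitTable, read_trait_table, write_trait_table

logger = logging.getLogger(__name__)

RECOVERY_TRAITS = list(GAS_EXCHANGE_TRAITS)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    out_dir: str = "results"
    input_table: str | None = None  # when None, simulation must be enabled
    # design
    n_families: int = 16
    replicates: int = 5
    blocks: int = 2
    # seeds and sampling effort
    seed: int = 0
    n_perm: int = 1000
    bootstrap: int = 1000
    alpha: float = 0.05
    profiles: str | None = None  # optional YAML with family profiles
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "indices": True,
            "stomatal": True,
            "anova": True,
            "multivariate": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.stages.get("simulate", False) and self.input_table is None:
            raise ValueError("config needs an input table or the simulate stage enabled")
        if self.input_table is not None and not self.stages.get("simulate", False):
            if not Path(self.input_table).exists():
                raise ValueError(f"input table not found: {self.input_table}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    """Independent, reproducible per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    for sub in ("tables", "indices", "models", "multivariate"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    inputs: list[Path] = []
    stages_run: list[str] = []

    def _run(stage: str, fn):
        logger.info("stage %s: start", stage)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        stages_run.append(stage)
        logger.info("stage %s: done", stage)

    table_path = out / "tables" / "table.csv"
    holder: dict = {}

    if config.stages.get("simulate", True):
        def _simulate():
            design = ExperimentDesign(
                n_families=config.n_families,
                replicates=config.replicates,
                blocks=config.blocks,
            )
            seed = _stage_seed(config.seed, "simulate")
            if config.profiles:
                profiles = profiles_from_yaml(config.profiles)
                inputs.append(Path(config.profiles))
            else:
                profiles = default_profiles(design, seed)
            table = simulate(design, profiles, seed=seed)
            write_trait_table(table, table_path)
            outputs.append(table_path)
            holder["table"] = table

        _run("simulate", _simulate)
    else:
        inputs.append(Path(config.input_table))
        holder["table"] = read_trait_table(config.input_table)

    table: TraitTable = holder["table"]

    if config.stages.get("indices", True):
        def _indices():
            im = build_index_matrix(table)
            holder["index_matrix"] = im
            path = out / "indices" / "indices.csv"
            im.matrix.to_csv(path)
            outputs.append(path)
            seed = _stage_seed(config.seed, "indices")
            rows = []
            for res_kind in ("PP", "RE"):
                cols = [c for c in im.matrix.columns if c.startswith(f"{res_kind}-")]
                for col in cols:
                    trait = col.split("-", 1)[1]
                    try:
                        stat, p = family_difference_test(
                            table, trait, res_kind, n_perm=config.n_perm, seed=seed
                        )
                    except ValueError as exc:
                        logger.warning("permutation test skipped for %s: %s", col, exc)
                        continue
                    rows.append({"index": col, "F_like": stat, "p": p, "n_perm": config.n_perm})
            tests_path = out / "indices" / "permutation_tests.csv"
            pd.DataFrame(rows).to_csv(tests_path, index=False)
            outputs.append(tests_path)

        _run("indices", _indices)

    if config.stages.get("stomatal", True):
        def _stomatal():
            fit = fit_loglinear(table)
            holder["fit"] = fit
            coef_path = out / "models" / "coefficients.csv"
            coefficient_report(fit).to_csv(coef_path, index=False)
            anova_path = out / "models" / "stomatal_anova.csv"
            sequential_anova(fit).to_csv(anova_path)
            outputs.extend([coef_path, anova_path])

        _run("stomatal", _stomatal)

    if config.stages.get("anova", True):
        def _anova():
            present = set(table.subset(phase="recovery")["trait"].unique())
            traits = [t for t in RECOVERY_TRAITS if t in present]
            results = anova_by_trait(table, traits, phase="recovery")
            frames = []
            for trait, res in results.items():
                frame = res.table.reset_index(names="term")
                frame.insert(0, "trait", trait)
                frame["shapiro_W"] = res.assumptions.shapiro_w
                frame["shapiro_p"] = res.assumptions.shapiro_p
                frame["levene_stat"] = res.assumptions.levene_stat
                frame["levene_p"] = res.assumptions.levene_p
                frames.append(frame)
            path = out / "models" / "recovery_anova.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            outputs.append(path)

        _run("anova", _anova)

    if config.stages.get("multivariate", True):
        def _multivariate():
            im = holder.get("index_matrix")
            if im is None:
                im = build_index_matrix(table)
            seed = _stage_seed(config.seed, "multivariate")
            tree = cluster_families(im.matrix.dropna(axis=1), B=config.bootstrap, seed=seed)
            mdir = out / "multivariate"
            (mdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
            tree.nodes.to_csv(mdir / "cluster_support.csv", index=False)
            features = build_family_features(table, im, fit=holder.get("fit"))
            features.to_csv(mdir / "features.csv")
            pca = pca_families(features)
            pd.DataFrame(
                {
                    "eigenvalue": pca.eigenvalues,
                    "variance_fraction": pca.variance_fractions,
                    "retained": pca.eigenvalues > 1.0,
                },
                index=pca.loadings.columns,
            ).to_csv(mdir / "pca_summary.csv")
            pca.loadings.to_csv(mdir / "pca_loadings.csv")
            pca.scores.to_csv(mdir / "pca_scores.csv")
            corr = correlation_matrix(features, alpha=config.alpha)
            corr.correlations.to_csv(mdir / "correlations.csv")
            corr.q_values.to_csv(mdir / "correlations_q.csv")
            corr.significant.to_csv(mdir / "correlations_significant.csv")
            outputs.extend(sorted(mdir.glob("*")))

        _run("multivariate", _multivariate)

    manifest = {
        "phenoplast_version": __version__,
        "config": asdict(config),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in stages_run},
        "stages_run": stages_run,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {p.relative_to(out).as_posix(): _sha256(p) for p in sorted(set(outputs))},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
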