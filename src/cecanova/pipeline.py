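"""Configured end-to-end runs: synth -> preprocess -> diversity ->
differential abundance -> sPLS-DA.

A run is fully described by a :class:`RunConfig` (YAML-serializable).
Every stage writes its tables under the output directory, and a manifest
records parameters, derived stage seeds and a SHA-256 digest of every
artifact, so re-running the same config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div_mod
from . import perm_anova, preprocess, splsda, synthetic
from .errors import CecanovaError, ParameterError
from .io_formats import (
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_count_table,
    write_metadata,
    write_taxonomy,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("synth", "preprocess", "diversity", "diffabund", "splsda")


@dataclass
class RunConfig:
    """All pipeline parameters. Defaults mirror the study's printed ones:
    depth filters 5000/10,000, 5% prevalence, 0.01% abundance, 1000
    permutations at FDR 0.05, 5-fold CV, at most 4 components."""

    # inputs: either a synth preset or paths to the three tables
    synth_preset: str | None = "full425"
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    # synth parameters
    n_otus: int = 963
    concentration: float = 200.0
    effects: list = field(default_factory=list)  # [otu_id, factor, log2fc] triples
    # preprocess
    min_sample_depth: int = 5000
    doubleton_max_total: int = 2
    min_prevalence: float = 0.05
    min_total_fraction: float = 0.0001
    css_quantile: float | None = None
    rarefy_depth: int = 10_000
    # inference
    n_perm: int = 1000
    alpha: float = 0.05
    feeding: str = "nested"
    # sPLS-DA (farm discrimination)
    keepX_grid: list = field(default_factory=lambda: [1, 5, 10, 25, 50, 70])
    max_ncomp: int = 4
    tune_repeats: int = 10
    eval_repeats: int = 1000
    cv_folds: int = 5
    # bookkeeping
    seed: int = 0
    out_dir: str = "cecanova_run"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return all parameter-domain violations (empty list = valid)."""
    bad: list[str] = []
    if cfg.synth_preset is None and not (cfg.counts_path and cfg.metadata_path):
        bad.append("either synth_preset or counts_path+metadata_path required")
    if cfg.synth_preset not in (None, "full425", "null"):
        bad.append(f"unknown synth preset {cfg.synth_preset!r}")
    if cfg.n_otus < 1:
        bad.append("n_otus must be >= 1")
    if cfg.concentration <= 0:
        bad.append("concentration must be > 0")
    if cfg.min_sample_depth < 0:
        bad.append("min_sample_depth must be >= 0")
    if not (0 < cfg.min_prevalence < 1):
        bad.append("min_prevalence must lie in (0, 1)")
    if not (0 < cfg.min_total_fraction < 1):
        bad.append("min_total_fraction must lie in (0, 1)")
    if cfg.css_quantile is not None and not (0 < cfg.css_quantile < 1):
        bad.append("css_quantile must lie in (0, 1)")
    if cfg.rarefy_depth < 1:
        bad.append("rarefy_depth must be >= 1")
    if cfg.n_perm < 1:
        bad.append("n_perm must be >= 1")
    if not (0 < cfg.alpha < 1):
        bad.append("alpha must lie in (0, 1)")
    if cfg.feeding not in ("nested", "averaged", "auto"):
        bad.append("feeding must be nested|averaged|auto")
    if not cfg.keepX_grid or any(k < 1 for k in cfg.keepX_grid):
        bad.append("keepX_grid must be a nonempty list of positive integers")
    if not (1 <= cfg.max_ncomp <= 4):
        bad.append("max_ncomp must lie in 1..4")
    if cfg.cv_folds < 2:
        bad.append("cv_folds must be >= 2")
    if cfg.tune_repeats < 1 or cfg.eval_repeats < 1:
        bad.append("repeat counts must be >= 1")
    return bad


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF,
                                 _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_frame(path: Path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return the artifact manifest."""
    violations = validate_config(cfg)
    if violations:
        raise ParameterError("invalid config: " + "; ".join(violations))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {},
                      "artifacts": {}}
    artifacts: dict[str, Path] = {}
    current = "setup"
    try:
        # ---- inputs -------------------------------------------------
        current = "synth"
        if cfg.synth_preset is not None:
            seed = _stage_seed(cfg.seed, "synth")
            manifest["stages"]["synth"] = {"seed": seed}
            effects = tuple(synthetic.EffectSpec(o, f, float(l))
                            for o, f, l in cfg.effects)
            params = synthetic.SimulationParams(
                n_otus=cfg.n_otus, concentration=cfg.concentration,
                effects=effects, seed=seed)
            table, _ = synthetic.generate_counts(params)
            tax = synthetic.generate_taxonomy(cfg.n_otus, seed=seed)
            meta = params.design
            write_count_table(out / "counts.tsv", table)
            write_metadata(out / "metadata.tsv", meta)
            write_taxonomy(out / "taxonomy.tsv", tax)
            artifacts.update({"counts": out / "counts.tsv",
                              "metadata": out / "metadata.tsv",
                              "taxonomy": out / "taxonomy.tsv"})
        else:
            meta = read_metadata(cfg.metadata_path)
            table, inline_tax = read_count_table(cfg.counts_path)
            tax = (read_taxonomy(cfg.taxonomy_path)
                   if cfg.taxonomy_path else inline_tax)

        # ---- preprocess --------------------------------------------
        current = "preprocess"
        seed = _stage_seed(cfg.seed, "preprocess")
        manifest["stages"]["preprocess"] = {"seed": seed}
        filtered = preprocess.remove_doubletons(
            preprocess.remove_low_depth_samples(table, cfg.min_sample_depth),
            cfg.doubleton_max_total)
        meta = meta[meta["sample_id"].isin(filtered.sample_ids)].reset_index(drop=True)
        analysed = preprocess.prevalence_abundance_filter(
            filtered, cfg.min_prevalence, cfg.min_total_fraction)
        css = preprocess.css_normalize(analysed, cfg.css_quantile)
        rare = preprocess.rarefy(filtered, cfg.rarefy_depth, seed=seed)
        write_count_table(out / "filtered.tsv", filtered)
        _write_frame(out / "css.tsv", css.to_frame())
        write_count_table(out / "rarefied.tsv", rare)
        artifacts.update({"filtered": out / "filtered.tsv",
                          "css": out / "css.tsv",
                          "rarefied": out / "rarefied.tsv"})
        pct = {}
        if tax is not None:
            for rank in ("phylum", "genus"):
                pct[rank] = preprocess.collapse_taxa(css, tax, rank)
                _write_frame(out / f"{rank}_pct.tsv", pct[rank])
                artifacts[f"{rank}_pct"] = out / f"{rank}_pct.tsv"

        # ---- diversity ---------------------------------------------
        current = "diversity"
        rare_meta = meta[meta["sample_id"].isin(rare.sample_ids)].reset_index(drop=True)
        alpha = div_mod.alpha_diversity(rare)
        contrasts_alpha = div_mod.alpha_contrasts(alpha, rare_meta, alpha=cfg.alpha)
        _write_frame(out / "alpha.tsv", alpha, index=False)
        _write_frame(out / "alpha_contrasts.tsv", contrasts_alpha, index=False)
        artifacts.update({"alpha": out / "alpha.tsv",
                          "alpha_contrasts": out / "alpha_contrasts.tsv"})

        # ---- differential abundance --------------------------------
        current = "diffabund"
        seed = _stage_seed(cfg.seed, "diffabund")
        manifest["stages"]["diffabund"] = {"seed": seed}
        levels: dict[str, pd.DataFrame] = {"otu": css.to_frame()}
        for rank, frame in pct.items():
            levels[rank] = frame
        for level, frame in levels.items():
            res = perm_anova.run_differential_abundance(
                frame, meta, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=seed,
                feeding=cfg.feeding)
            _write_frame(out / f"diffabund_{level}.tsv", res, index=False)
            artifacts[f"diffabund_{level}"] = out / f"diffabund_{level}.tsv"

        # ---- sPLS-DA (farm discrimination) --------------------------
        current = "splsda"
        seed = _stage_seed(cfg.seed, "splsda")
        manifest["stages"]["splsda"] = {"seed": seed}
        Xdf = css.to_frame().T.loc[list(meta["sample_id"])]
        y = meta.set_index("sample_id").loc[Xdf.index, "farm"].to_numpy()
        tuned = splsda.tune_splsda(Xdf, y, cfg.keepX_grid,
                                   max_ncomp=cfg.max_ncomp, folds=cfg.cv_folds,
                                   repeats=cfg.tune_repeats, seed=seed)
        model = splsda.fit_splsda(Xdf, y, ncomp=tuned["ncomp"],
                                  keepX=tuned["keepX"])
        perf = splsda.evaluate_splsda(Xdf, y, tuned["ncomp"], tuned["keepX"],
                                      folds=cfg.cv_folds,
                                      repeats=cfg.eval_repeats, seed=seed + 1)
        scores = pd.DataFrame(model.scores, index=Xdf.index,
                              columns=[f"comp{h + 1}" for h in range(model.ncomp)])
        scores.insert(0, "class", y)
        _write_frame(out / "splsda_scores.tsv", scores)
        _write_frame(out / "splsda_stability.tsv", perf.stability)
        summary = {
            "ncomp": tuned["ncomp"], "keepX": tuned["keepX"],
            "explained_variance": [float(v) for v in model.explained_variance],
            "overall_ber_mean": perf.overall_ber[0],
            "overall_ber_sd": perf.overall_ber[1],
            "per_class_ber": {str(k): list(v) for k, v in perf.per_class_ber.items()},
        }
        (out / "splsda_summary.json").write_text(json.dumps(summary, indent=2))
        artifacts.update({"splsda_scores": out / "splsda_scores.tsv",
                          "splsda_stability": out / "splsda_stability.tsv",
                          "splsda_summary": out / "splsda_summary.json"})
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {current}\ncause: {exc!r}\n")
        raise CecanovaError(f"pipeline failed at stage {current!r}: {exc}") from exc

    manifest["artifacts"] = {k: {"path": str(p), "sha256": _sha256(p)}
                             for k, p in artifacts.items()}
    cfg.to_yaml(out / "config.yml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
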