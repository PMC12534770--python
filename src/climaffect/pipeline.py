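"""End-to-end pipeline: simulate-or-ingest, score, index, merge, model.

A run is described by one YAML config (see ``data/demo_config.yaml``).  All
stage inputs are validated before any computation starts, stages execute in
dependency order, and every run writes a manifest recording the config,
input hashes, seeds, row counts and drop counts, so each number in a report
can be traced to its inputs.  Reruns with the same config and inputs are
identical given the same seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .correlation import correlation_matrix
from .lexicon import (
    load_toy_lexicon,
    load_toy_proenv_lexicon,
    read_lexicon,
    read_proenv_lexicon,
    score_posts,
)
from .mediation import PathModelSpec, bootstrap_effects
from .merging import merge_analysis
from .regression import fit_logistic_nested, fit_moderation, vif_screen
from .simulate import (
    RegionClimate,
    StructuralTruth,
    SyntheticConfig,
    generate_posts,
    generate_vulnerability,
    generate_weather,
)
from .weather import build_climatology, compute_indicators, read_weather_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]

DEFAULT_CORRELATION_VARS = {
    "extreme_hot": "binary",
    "extreme_cold": "binary",
    "extreme_wet": "binary",
    "temp_change": "continuous",
    "precip_change": "continuous",
    "ewb": "continuous",
    "anger": "continuous",
    "anxiety": "continuous",
    "sadness": "continuous",
    "affiliation": "continuous",
    "analytic": "continuous",
    "somatosensory": "continuous",
    "pro_env": "binary",
}

VULN_FLAGS = [
    "population_density_high",
    "exposure_high",
    "sensitivity_high",
    "adaptability_high",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    output_dir: str = "climaffect_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    weather_path: str | None = None
    posts_path: str | None = None
    vulnerability_path: str | None = None
    lexicon_path: str | None = None
    proenv_lexicon_path: str | None = None
    percentile_window: str = "year"
    exposure: str = "extreme_hot"
    n_boot: int = 1000
    ci_level: float = 0.95
    moderation_exposure: str = "temp_change"
    moderation_moderator: str = "season"
    correlation_variables: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATION_VARS))

    def validate(self) -> None:
        """Fail fast: every enabled stage's inputs must resolve up front."""
        for label, p in (
            ("weather", self.weather_path),
            ("posts", self.posts_path),
            ("vulnerability", self.vulnerability_path),
            ("lexicon", self.lexicon_path),
            ("pro-environmental lexicon", self.proenv_lexicon_path),
        ):
            if p is not None and not Path(p).is_file():
                raise PipelineError(f"{label} file not found: {p}")
        if self.exposure not in ("extreme_hot", "temp_change"):
            raise PipelineError(f"unknown exposure {self.exposure!r}")
        if self.posts_path is None and self.weather_path is not None:
            raise PipelineError(
                "synthetic posts require synthetic weather (omit weather_path)"
            )


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _synth_config(cfg: RunConfig) -> SyntheticConfig:
    sim = dict(cfg.simulate)
    sim.setdefault("seed", cfg.seed)
    sim.setdefault("exposure", cfg.exposure)
    if "region_climate" in sim:
        sim["region_climate"] = [RegionClimate(**rc) for rc in sim["region_climate"]]
    if "structural" in sim:
        st = dict(sim["structural"])
        for key in ("a", "b", "mediator_intercepts", "mediator_resid_sds", "logit_coefs"):
            if key in st:
                st[key] = tuple(st[key])
        sim["structural"] = StructuralTruth(**st)
    return SyntheticConfig(**sim)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest dict.

    Outputs land in ``cfg.output_dir``: the indicator table, scored posts,
    analysis table, correlation long table, mediation effects and fit block,
    moderation and nested-logistic coefficient tables, and ``manifest.json``.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in vars(cfg).items()},
        "input_hashes": {},
        "counts": {},
    }
    for label, p in (
        ("weather", cfg.weather_path),
        ("posts", cfg.posts_path),
        ("vulnerability", cfg.vulnerability_path),
        ("lexicon", cfg.lexicon_path),
        ("proenv_lexicon", cfg.proenv_lexicon_path),
    ):
        if p is not None:
            manifest["input_hashes"][label] = _sha256(p)

    lexicon = read_lexicon(cfg.lexicon_path) if cfg.lexicon_path else load_toy_lexicon()
    pel = (
        read_proenv_lexicon(cfg.proenv_lexicon_path)
        if cfg.proenv_lexicon_path
        else load_toy_proenv_lexicon()
    )

    scfg = _synth_config(cfg)
    if cfg.weather_path:
        weather = read_weather_table(cfg.weather_path)
        baseline_start = weather["date"].min()
        baseline_end = weather["date"].max()
    else:
        weather = generate_weather(scfg)
        baseline_start = scfg.baseline_start
        baseline_end = pd.Timestamp(scfg.date_start) - pd.Timedelta(days=1)
    clim = build_climatology(
        weather, baseline_start, baseline_end, window=cfg.percentile_window
    )
    indicators = compute_indicators(weather, clim)
    indicators.to_csv(out / "weather_indicators.csv", index=False)
    manifest["counts"]["weather_rows"] = len(weather)

    if cfg.posts_path:
        posts = pd.read_csv(cfg.posts_path)
        scored = score_posts(posts, lexicon, pel=pel)
    else:
        scored = generate_posts(scfg, indicators)
    scored.to_csv(out / "scored_posts.csv", index=False)
    manifest["counts"]["posts"] = len(scored)

    if cfg.vulnerability_path:
        vuln = pd.read_csv(cfg.vulnerability_path)
    else:
        vuln = generate_vulnerability(scfg)
    vuln.to_csv(out / "vulnerability.csv", index=False)

    analysis, report = merge_analysis(scored, indicators, vuln)
    for col in VULN_FLAGS:
        analysis[col] = analysis[col].astype(float)
    analysis.to_csv(out / "analysis_table.csv", index=False)
    manifest["counts"].update(
        {
            "analysis_rows": report.n_matched,
            "dropped_no_weather": report.n_dropped_no_weather,
            "dropped_no_vulnerability": report.n_dropped_no_vulnerability,
        }
    )

    corr_vars = {
        k: v for k, v in cfg.correlation_variables.items() if k in analysis.columns
    }
    corr = correlation_matrix(analysis, corr_vars)
    corr.to_long().to_csv(out / "correlations.csv", index=False)

    med_spec = PathModelSpec(
        exposure=cfg.exposure,
        n_boot=cfg.n_boot,
        ci_level=cfg.ci_level,
        seed=cfg.seed,
    )
    med = bootstrap_effects(analysis, med_spec)
    med.to_frame().to_csv(out / "mediation_effects.csv", index=False)
    with open(out / "mediation_fit.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "fit": med.fit,
                "n_used": med.n_used,
                "n_boot": med.n_boot,
                "ci_level": med.ci_level,
                "seed": med.seed,
            },
            fh,
            indent=2,
        )

    mod = fit_moderation(
        analysis,
        outcome="ewb",
        exposure=cfg.moderation_exposure,
        moderator=cfg.moderation_moderator,
        moderator_type="factor" if cfg.moderation_moderator == "season" else "numeric",
    )
    mod.table.to_csv(out / "moderation.csv")

    blocks = [
        [cfg.exposure],
        ["ewb"],
        ["affiliation", "analytic", "somatosensory"],
        VULN_FLAGS,
    ]
    screened = [t for b in blocks for t in b]
    vif_table, removed = vif_screen(analysis[screened].astype(float))
    manifest["vif_removed"] = removed
    vif_table.to_csv(out / "vif.csv")
    blocks = [[t for t in b if t not in removed] for b in blocks]
    nested = fit_logistic_nested(analysis, "pro_env", blocks)
    for i, fit in enumerate(nested, start=1):
        fit.table.to_csv(out / f"proenv_model{i}.csv")
    manifest["proenv_pseudo_r2"] = [f.pseudo_r2 for f in nested]

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
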