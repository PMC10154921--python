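"""End-to-end orchestration: data → networks → metrics → stress response.

`run_pipeline` executes the full analysis:

1. read (or synthesize) the trait table and community data;
2. binarize traits and pool plots into one community per site-treatment;
3. score every trait pair's co-occurrence and apply the expected-
   co-occurrence filter;
4. build the weighted trait networks and score the pooled eigencentrality;
5. tabulate per-network metrics, then effect sizes, t-tests, quantile
   fits and the variance-convergence summary.

All artifacts (CSVs, network exports, figures, a JSON run manifest) are
written under the configured output directory. All randomness flows from
the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import __version__
from .cooccurrence import filter_trait_pairs, pairs_to_frame, score_trait_pairs
from .stress_response import (
    DEFAULT_TAUS,
    convergence_summary,
    effect_sizes,
    fits_to_frame,
    metric_tests,
    quantile_fits,
    COUNT_METRICS,
)
from .synthetic_data import GeneratorConfig, generate_dataset
from .trait_data import (
    CommunityData,
    TraitMatrix,
    binarize_traits,
    pool_all,
    read_community,
    read_trait_table,
    write_community,
    write_trait_table,
)
from .trait_network import (
    TraitNetwork,
    build_network,
    export_network,
    metrics_table,
    pooled_eigencentrality,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one full run (YAML-mirrored; CLI flags win)."""

    trait_path: str | None = None
    community_path: str | None = None
    covariates_path: str | None = None
    synthetic: bool = False
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    binarize_threshold: float = 0.0
    e_threshold: float = 1.0
    sig_alpha: float | None = None
    exclude_within_trait: bool = False
    eigencentrality_mode: str = "per_component_scaled"
    eigencentrality_iterations: int = 100
    weighted: bool = False
    taus: tuple[float, ...] = DEFAULT_TAUS
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    export_format: str = "gexf"
    make_plots: bool = True

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.taus)
        if any(not 0 < t < 1 for t in taus):
            raise ValueError("quantiles must lie strictly within (0, 1)")
        if sorted(set(taus)) != list(taus):
            raise ValueError("quantiles must be sorted and unique")
        self.taus = taus

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


@dataclass
class ResultsBundle:
    """Everything one run computes."""

    metrics: pd.DataFrame
    effects: pd.DataFrame
    tests: pd.DataFrame
    pairs: pd.DataFrame
    fits_by_metric: dict
    convergence: pd.DataFrame
    networks: list[TraitNetwork]
    scores: dict
    truth: dict | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("load")
def _load_inputs(cfg: PipelineConfig) -> tuple[TraitMatrix, CommunityData, dict | None]:
    if cfg.synthetic:
        gen = dataclasses.replace(cfg.generator, seed=cfg.seed)
        ds = generate_dataset(gen)
        return ds.traits, ds.community, ds.truth
    if cfg.trait_path is None or cfg.community_path is None:
        raise ValueError("trait_path and community_path required unless synthetic")
    traits = read_trait_table(cfg.trait_path)
    community = read_community(cfg.community_path, cfg.covariates_path)
    return traits, community, None


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Execute the full analysis and (optionally) write all artifacts."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    traits, community, truth = _load_inputs(cfg)
    traits = binarize_traits(traits, cfg.binarize_threshold)

    communities = _stage("pool")(pool_all)(community)
    logger.info("pooled %d site-treatment communities", len(communities))

    networks: list[TraitNetwork] = []
    pair_frames = []
    for com in communities:
        stats = _stage("cooccurrence")(score_trait_pairs)(com, traits)
        retained = filter_trait_pairs(
            stats, e_threshold=cfg.e_threshold, sig_alpha=cfg.sig_alpha,
            exclude_within_trait=cfg.exclude_within_trait, traits=traits,
        )
        pair_frames.append(
            pairs_to_frame(retained, site=com.site, treatment=com.treatment)
        )
        networks.append(
            _stage("network")(build_network)(retained, com.site, com.treatment, traits)
        )
    pair_frames = [f for f in pair_frames if not f.empty]
    pairs = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames else pairs_to_frame([])
    )

    scores = _stage("eigencentrality")(pooled_eigencentrality)(
        [n for n in networks if n.n_nodes > 0],
        iterations=cfg.eigencentrality_iterations,
        weighted=cfg.weighted,
        mode=cfg.eigencentrality_mode,
    )
    metrics = _stage("metrics")(metrics_table)(networks, scores)

    effects = _stage("effects")(effect_sizes)(metrics)
    tests = _stage("tests")(metric_tests)(effects)

    fits_by_metric: dict = {}
    conv_rows = []
    for metric in COUNT_METRICS:
        sub = effects[(effects["metric"] == metric) & effects["effect"].notna()]
        x = sub["baseline_complexity"].to_numpy()
        y = sub["effect"].to_numpy()
        fits = _stage("quantile")(quantile_fits)(x, y, cfg.taus)
        fits_by_metric[metric] = fits
        cs = convergence_summary(fits, x)
        conv_rows.append({
            "metric": metric, "x_min": cs.x_min, "x_max": cs.x_max,
            "spread_at_min": cs.spread_at_min, "spread_at_max": cs.spread_at_max,
            "spread_difference": cs.spread_difference,
        })
    convergence = pd.DataFrame(conv_rows)

    bundle = ResultsBundle(
        metrics=metrics, effects=effects, tests=tests, pairs=pairs,
        fits_by_metric=fits_by_metric, convergence=convergence,
        networks=networks, scores=scores, truth=truth,
    )
    if cfg.out_dir is not None:
        _write_outputs(cfg, bundle, traits, community)
    return bundle


# ---------------------------------------------------------------------------
# Artifacts


@_stage("write")
def _write_outputs(
    cfg: PipelineConfig,
    bundle: ResultsBundle,
    traits: TraitMatrix,
    community: CommunityData,
) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.metrics.to_csv(out / "metrics.csv", index=False)
    bundle.effects.to_csv(out / "effects.csv", index=False)
    bundle.tests.to_csv(out / "tests.csv", index=False)
    bundle.pairs.to_csv(out / "retained_pairs.csv", index=False)
    fits_to_frame(bundle.fits_by_metric).to_csv(out / "quantile_fits.csv", index=False)
    bundle.convergence.to_csv(out / "convergence.csv", index=False)
    _write_report(out / "report.txt", bundle)

    if cfg.synthetic:
        write_trait_table(traits, out / "trait_table.csv")
        write_community(community, out / "community.csv", out / "covariates.csv")
        if bundle.truth is not None:
            (out / "truth.json").write_text(
                json.dumps(bundle.truth, indent=2, sort_keys=True)
            )

    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for net in bundle.networks:
        if net.n_nodes == 0:
            continue
        path = net_dir / f"{net.site}_{net.treatment}.{cfg.export_format}"
        export_network(net, bundle.scores, path, fmt=cfg.export_format,
                       layout_seed=cfg.seed)

    if cfg.make_plots:
        _plot_effect_boxes(bundle.effects, out / "effects_boxplot.png")
        _plot_quantile_fans(bundle.effects, bundle.fits_by_metric,
                            out / "effects_vs_complexity.png")
        if community.covariates is not None:
            _plot_covariate_biplots(bundle.metrics, community.covariates,
                                    out / "complexity_vs_covariates.png")

    manifest = {
        "package": "traitnet",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("artifacts written to %s", out)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["taus"] = list(cfg.taus)
    return d


def _write_report(path: Path, bundle: ResultsBundle) -> None:
    lines = ["trait network stress-response report", "=" * 38, ""]
    ctrl = bundle.metrics[bundle.metrics["treatment"] == "control"]
    if not ctrl.empty:
        lines.append(
            f"baseline network complexity (control mean eigencentrality): "
            f"{ctrl['mean_eigencentrality'].min():.3f}"
            f"-{ctrl['mean_eigencentrality'].max():.3f} "
            f"across {len(ctrl)} sites"
        )
    lines.append(f"networks built: {len(bundle.metrics)}")
    lines.append("")
    lines.append("t-tests on effect sizes (vs control = 1):")
    for _, r in bundle.tests.iterrows():
        lines.append(
            f"  {r['metric']:<15s} {r['test']:<18s} t={r['t']:+.3f}  p={r['p']:.5f}"
        )
    lines.append("")
    lines.append("quantile-spread convergence (positive difference = converging):")
    for _, r in bundle.convergence.iterrows():
        lines.append(
            f"  {r['metric']:<15s} spread {r['spread_at_min']:.3f} -> "
            f"{r['spread_at_max']:.3f}  (difference {r['spread_difference']:+.3f})"
        )
    path.write_text("\n".join(lines) + "\n")


def _plot_effect_boxes(effects: pd.DataFrame, path: Path) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    for ax, metric in zip(axes.ravel(), COUNT_METRICS):
        sub = effects[(effects["metric"] == metric) & effects["effect"].notna()]
        data = [sub.loc[sub["level"] == lv, "effect"] for lv in ("medium", "high")]
        ax.boxplot(data, tick_labels=["medium", "high"], showmeans=True)
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_title(metric)
        ax.set_ylabel("effect size (treatment / control)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_quantile_fans(
    effects: pd.DataFrame, fits_by_metric: Mapping, path: Path
) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    colors = {"medium": "tab:orange", "high": "tab:pink"}
    for ax, metric in zip(axes.ravel(), COUNT_METRICS):
        sub = effects[(effects["metric"] == metric) & effects["effect"].notna()]
        for lv, grp in sub.groupby("level"):
            ax.scatter(grp["baseline_complexity"], grp["effect"],
                       s=14, color=colors.get(lv, "k"), label=lv, alpha=0.7)
        grid = np.linspace(sub["baseline_complexity"].min(),
                           sub["baseline_complexity"].max(), 50)
        for f in fits_by_metric.get(metric, []):
            ax.plot(grid, f.predict(grid), ls="--", lw=0.8, color="grey")
        ax.axhline(1.0, color="k", lw=0.6)
        ax.set_title(metric)
        ax.set_xlabel("baseline network complexity")
        ax.set_ylabel("effect size")
    handles, labels = axes[0, 0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_covariate_biplots(
    metrics: pd.DataFrame, covariates: pd.DataFrame, path: Path
) -> None:
    ctrl = metrics[metrics["treatment"] == "control"].set_index("site")
    joined = ctrl.join(covariates, how="inner")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (col, label, log) in zip(axes, [
        ("mean_par", "mean PAR (µmol photons m⁻² s⁻¹)", False),
        ("porewater_nh4", "porewater NH4 (log scale)", True),
    ]):
        if col not in joined.columns:
            continue
        ax.scatter(joined[col], joined["mean_eigencentrality"], s=18)
        if log:
            ax.set_xscale("log")
        ax.set_xlabel(label)
        ax.set_ylabel("baseline network complexity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
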