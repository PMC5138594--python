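"""Config-driven runs: generation → synthetic observers → analysis.

A run is described by a JSON :class:`RunConfig` (experiment id, canvas and
texture parameters, observer model, master seed, output directory) and
produces a design CSV, a sampled subset of stimulus PNGs with JSON
sidecars, a synthetic behaviour CSV, analysis tables (CSV + JSON), a
summary figure, and a manifest.  All randomness descends from the master
seed through named ``numpy`` seed sequences, so re-running a config
reproduces every table bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    BayesConfig,
    code_depth_responses,
    control_relative,
    preprocess_rt,
    summarize_scores,
)
from .background import (
    DEG_PER_PX,
    LeafShapeParams,
    SceneCanvas,
    ShadowSpec,
    render_background,
    save_scene,
)
from .colors import PatchColorRule, filter_population, synth_forest_population
from .designs import (
    design_exp1,
    design_exp2,
    design_exp3,
    design_to_frame,
)
from .observers import ObserverModel, simulate_depth_dataset, simulate_rt_dataset
from .texture import (
    FilterSpec,
    clear_central_band,
    compose_stimulus,
    make_target,
)
from .transect import load_image, transect_profile

__all__ = ["RunConfig", "run_experiment", "main"]

_DESIGNS = {1: design_exp1, 2: design_exp2, 3: design_exp3}


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    experiment: int = 1
    seed: int = 0
    outdir: str = "run"
    canvas_width: int = 3500
    canvas_height: int = 1170
    deg_per_px: float = DEG_PER_PX
    n_leaves: int = 15_000
    population_n: int = 10_000
    target_length_px: float = 350.0
    n_stimuli: int = 2  # how many trials get rendered to PNG
    filter: dict = field(default_factory=dict)
    leaf: dict = field(default_factory=dict)
    shadow: dict = field(default_factory=dict)
    observer_effects: dict = field(default_factory=dict)
    observer: dict = field(default_factory=dict)
    depth_shift: dict = field(default_factory=dict)
    depth_thresholds: tuple[float, float] = (-0.5, 0.5)
    cauchy_r: float = 1.0
    n_boot: int = 10_000

    def __post_init__(self) -> None:
        if self.experiment not in _DESIGNS:
            raise ValueError(f"experiment must be one of {sorted(_DESIGNS)}")
        self.seed = int(self.seed)
        for key in ("filter", "leaf", "shadow"):
            spec_cls = {"filter": FilterSpec, "leaf": LeafShapeParams,
                        "shadow": ShadowSpec}[key]
            try:
                spec_cls(**getattr(self, key))
            except TypeError as exc:
                raise ValueError(f"invalid {key} parameters: {exc}") from exc

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "seed" not in data:
            raise ValueError("config must set a master seed")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "depth_thresholds" in data:
            data["depth_thresholds"] = tuple(data["depth_thresholds"])
        return cls(**data)


def _rng(cfg: RunConfig, *key: str | int) -> np.random.Generator:
    """A named child generator of the master seed (parallel-safe splitting).

    Keys are mapped through CRC32 so the split is stable across processes.
    """
    import zlib

    spawn = tuple(
        zlib.crc32(str(k).encode()) & 0x7FFFFFFF for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=spawn))


def _default_effects(cfg: RunConfig, design) -> dict[str, float]:
    labels = {t.condition.edge.label for t in design}
    effects = {label: 0.0 for label in labels}
    effects.update(cfg.observer_effects)
    return effects


def run_experiment(cfg: RunConfig) -> dict:
    """Execute a full run and return the manifest (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "files": {},
    }

    design = _DESIGNS[cfg.experiment](_rng(cfg, "design"))
    design_path = out / "design.csv"
    design_to_frame(design).to_csv(design_path, index=False)
    manifest["files"]["design"] = design_path.name

    pop = filter_population(
        synth_forest_population(cfg.population_n, _rng(cfg, "population"))
    )
    filt = FilterSpec(**cfg.filter)
    leaf = LeafShapeParams(**cfg.leaf)
    shadow = ShadowSpec(**cfg.shadow)
    rule = PatchColorRule()

    stim_names = []
    for trial in design[: cfg.n_stimuli]:
        rng = np.random.default_rng(trial.seed)
        canvas = SceneCanvas.uniform(
            cfg.canvas_width, cfg.canvas_height, 0.5, cfg.deg_per_px
        )
        bg = render_background(
            canvas,
            cfg.n_leaves,
            pop,
            rng,
            shadows=trial.condition.shadows,
            shadow_spec=shadow,
            leaf_params=leaf,
        )
        if cfg.experiment == 3:
            bg = clear_central_band(bg, canvas, (4.49, 13.80))
        target = make_target(
            pop, rule, filt, trial.condition.edge,
            cfg.target_length_px, trial.orientation, rng,
        )
        stim = compose_stimulus(
            bg, target, trial.cell, rng,
            condition=(trial.condition.edge, trial.condition.shadows),
        )
        name = f"stimulus_{trial.index:03d}.png"
        save_scene(
            stim.canvas,
            out / name,
            {
                "trial": trial.index,
                "seed": trial.seed,
                "edge": trial.condition.edge.label,
                "shadows": trial.condition.shadows,
                "cell": str(trial.cell),
                "target_bbox": list(stim.target_bbox),
            },
        )
        stim_names.append(name)
    manifest["files"]["stimuli"] = stim_names

    cfg_bayes = BayesConfig(cauchy_r=cfg.cauchy_r)
    if cfg.experiment in (1, 2):
        model = ObserverModel(
            condition_effects=_default_effects(cfg, design), **cfg.observer
        )
        behaviour = simulate_rt_dataset(design, model, _rng(cfg, "behaviour"))
        scores = control_relative(preprocess_rt(behaviour))
    else:
        shift = {t.condition.edge.label: 0.0 for t in design}
        shift.update(cfg.depth_shift)
        behaviour = simulate_depth_dataset(
            design, shift, cfg.depth_thresholds, _rng(cfg, "behaviour")
        )
        scores = control_relative(code_depth_responses(behaviour))
    behaviour_path = out / "behaviour.csv"
    behaviour.to_csv(behaviour_path, index=False)
    manifest["files"]["behaviour"] = behaviour_path.name

    summary = summarize_scores(
        scores, _rng(cfg, "bootstrap"), cfg=cfg_bayes, n_boot=cfg.n_boot
    )
    summary_path = out / "analysis.csv"
    summary.to_csv(summary_path, index=False)
    with open(out / "analysis.json", "w") as fh:
        json.dump(summary.to_dict(orient="records"), fh, indent=2)
    manifest["files"]["analysis"] = [summary_path.name, "analysis.json"]

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = None
    try:
        from .analysis import plot_condition_scores

        ax = plot_condition_scores(
            summary, title=f"Experiment {cfg.experiment} (seed {cfg.seed})"
        )
        ax.figure.tight_layout()
        fig_path = out / "summary.png"
        ax.figure.savefig(fig_path, dpi=120)
        manifest["files"]["figure"] = fig_path.name
    finally:
        if ax is not None:
            plt.close(ax.figure)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Chatty logging to stderr.")
@click.pass_context
def main(ctx, verbose):
    """Camouflage stimulus generation, simulation and analysis."""
    ctx.obj = {"verbose": verbose}


def _load_cfg(config_path: str) -> RunConfig:
    return RunConfig.from_json(config_path)


@main.command("run-all")
@click.argument("config_path", type=click.Path(exists=True))
def run_all_cmd(config_path):
    """Run design → stimuli → simulation → analysis from a JSON config."""
    manifest = run_experiment(_load_cfg(config_path))
    click.echo(json.dumps({"outdir": manifest["config"]["outdir"],
                           "files": manifest["files"]}, indent=2))


@main.command("design")
@click.argument("config_path", type=click.Path(exists=True))
def design_cmd(config_path):
    """Write the trial design CSV only."""
    cfg = _load_cfg(config_path)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = _DESIGNS[cfg.experiment](_rng(cfg, "design"))
    design_to_frame(design).to_csv(out / "design.csv", index=False)
    click.echo(f"{len(design)} trials -> {out / 'design.csv'}")


@main.command("generate-stimuli")
@click.argument("config_path", type=click.Path(exists=True))
def generate_cmd(config_path):
    """Render the configured subset of stimulus PNGs (via a full run)."""
    cfg = _load_cfg(config_path)
    manifest = run_experiment(cfg)
    click.echo("\n".join(manifest["files"]["stimuli"]))


@main.command("simulate")
@click.argument("config_path", type=click.Path(exists=True))
def simulate_cmd(config_path):
    """Simulate synthetic-observer behaviour (design + behaviour CSVs)."""
    cfg = _load_cfg(config_path)
    cfg.n_stimuli = 0
    run_experiment(cfg)
    click.echo(str(Path(cfg.outdir) / "behaviour.csv"))


@main.command("analyze")
@click.argument("config_path", type=click.Path(exists=True))
def analyze_cmd(config_path):
    """Run the statistical chain and print the summary table."""
    cfg = _load_cfg(config_path)
    cfg.n_stimuli = 0
    run_experiment(cfg)
    click.echo(pd.read_csv(Path(cfg.outdir) / "analysis.csv").to_string())


@main.command("transect")
@click.argument("image_path", type=click.Path(exists=True))
@click.option("--start", nargs=2, type=float, required=True)
@click.option("--end", nargs=2, type=float, required=True)
@click.option("--diameter", type=int, default=7, show_default=True)
@click.option("--out", "out_path", type=click.Path(), default="transect.csv")
def transect_cmd(image_path, start, end, diameter, out_path):
    """Disc-averaged luminance transect across a photographed boundary."""
    profile = transect_profile(load_image(image_path), start, end, diameter)
    profile.to_csv(out_path)
    if profile.truncated:
        click.echo("warning: disc truncated at the image border", err=True)
    click.echo(out_path)


if __name__ == "__main__":
    main()
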