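"""Config-driven orchestration: simulate / load, preprocess, analyze, compare.

A run is described by a structured-text (YAML) config with exactly one input
source (a track table or a simulation block) and optional preprocessing and
analysis parameters. Outputs are CSV tables plus a JSON manifest recording
versions, seeds, parameters and exclusion counts. Defaults mirror the study
conventions: 45 s sampling, 30-step minimum track length, 25 CDF bins,
19.5-min speed blocks, quintile speed classes, 400-point PSD padding,
5% D_eff speed bins, decile persistence bins.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffusion, ensemble, kinematics, simulate
from importlib.metadata import version as _pkg_version
from .io import TrajectorySet, preprocess, read_tracks, write_tracks

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1

DEFAULT_ANALYSES = (
    "summaries",
    "msd",
    "psd",
    "bouts",
    "ks",
    "speed_classes",
    "switching",
    "coupling",
    "deff",
    "scaling",
)


class ConfigError(ValueError):
    """A run config violates the schema; the message lists offending keys."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (see module docstring for defaults)."""

    input_path: str | None = None
    simulation: dict | None = None
    min_steps: int = 30
    fill_gaps: bool = True
    gap_mode: str = "split"
    subsample_factor: int = 1
    analyses: tuple = DEFAULT_ANALYSES
    seed: int = 0
    n_boot: int = 1000
    n_perm: int = 1000
    max_lag: float | None = None
    block_minutes: float = 19.5
    ks_alpha: float = 0.01
    n_classes: int = 5
    deff_taus: list | None = None
    deff_bin_frac: float = 0.05
    coupling_bins: int = 10

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(raw) - known - {"schema_version"})
        if bad:
            raise ConfigError(f"unknown config keys: {bad}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        has_input = cfg.input_path is not None
        has_sim = cfg.simulation is not None
        if has_input == has_sim:
            raise ConfigError(
                "config must contain exactly one of 'input_path' or 'simulation'"
            )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_mapping(raw)


def _population_from_dict(block: dict, seed: int) -> simulate.PopulationParams:
    block = dict(block)
    coupling = block.pop("coupling", {"model": "SPC", "alpha": 4.0, "beta": 0.5})
    model = coupling.get("model", "SPC").upper()
    if model == "SPC":
        coup = simulate.SPC(alpha=coupling.get("alpha", 4.0), beta=coupling.get("beta", 0.5))
    elif model == "UPT":
        coup = simulate.UPT(P0=coupling.get("P0", 1.5))
    else:
        raise ConfigError(f"unknown coupling model {model!r}")
    block.setdefault("seed", seed)
    return simulate.PopulationParams(coupling=coup, **block)


def _load_input(cfg: RunConfig) -> tuple[TrajectorySet, pd.DataFrame | None, str]:
    if cfg.input_path is not None:
        tracks = read_tracks(cfg.input_path)
        digest = hashlib.sha256(Path(cfg.input_path).read_bytes()).hexdigest()
        return tracks, None, digest
    pop = _population_from_dict(cfg.simulation, cfg.seed)
    tracks, truth = simulate.simulate_observed(pop)
    digest = hashlib.sha256(repr(pop).encode()).hexdigest()
    return tracks, truth, digest


def run_pipeline(config: RunConfig | dict | str | Path, out_dir: str | Path) -> Path:
    """Run the requested analyses and write CSV outputs plus a manifest.

    Analyses that cannot run on the given tracks (e.g. speed switching when
    no track spans two blocks) are skipped with a logged warning rather than
    failing the run.
    """
    if isinstance(config, (str, Path)):
        cfg = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = RunConfig.from_mapping(config)
    else:
        cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version("cellmotility"),
        "schema_version": CONFIG_SCHEMA_VERSION,
        "config": {k: v for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "counts": {},
        "skipped": [],
    }
    rng_seq = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["msd", "speed_classes", "switching", "coupling", "deff"], rng_seq.spawn(5)
        )
    }
    manifest["derived_seeds"] = seeds

    raw_tracks, truth, digest = _load_input(cfg)
    manifest["input_hash"] = digest
    manifest["counts"]["tracks_raw"] = len(raw_tracks)
    if truth is not None:
        truth_out = truth.copy()
        truth_out["switch_times"] = truth_out["switch_times"].map(json.dumps)
        truth_out.to_csv(out / "ground_truth.csv", index=False)
        write_tracks(raw_tracks, out / "tracks.csv")

    tracks = preprocess(raw_tracks, cfg.min_steps, cfg.fill_gaps, cfg.gap_mode)
    if cfg.subsample_factor > 1:
        from .io import subsample

        tracks = subsample(tracks, cfg.subsample_factor)
        tracks = preprocess(tracks, cfg.min_steps, fill_gaps=False, gap_mode=cfg.gap_mode)
    manifest["counts"]["tracks_analyzed"] = len(tracks)
    if len(tracks) == 0:
        raise ValueError("no tracks survive preprocessing")

    summaries = kinematics.summarize_set(tracks)
    if "summaries" in cfg.analyses:
        summaries.to_csv(out / "summaries.csv", index=False)
    manifest["counts"]["tracks_without_persistence"] = int(
        (~np.isfinite(summaries["persistence_time"])).sum()
    )

    def attempt(name, fn):
        if name not in cfg.analyses:
            return None
        try:
            return fn()
        except ValueError as err:
            logger.warning("analysis %s skipped: %s", name, err)
            manifest["skipped"].append({"analysis": name, "reason": str(err)})
            return None

    msd = attempt(
        "msd",
        lambda: ensemble.msd_curve(
            tracks, max_lag=cfg.max_lag, n_boot=cfg.n_boot, seed=seeds["msd"]
        ),
    )
    if msd is not None:
        msd.to_frame().to_csv(out / "msd.csv", index=False)
        try:
            fit = ensemble.fit_msd(msd)
            manifest["msd_fit"] = {"S": fit.S, "P": fit.P, "sigma2": fit.sigma2}
        except (ensemble.FitError, ValueError) as err:
            manifest["skipped"].append({"analysis": "msd_fit", "reason": str(err)})

    psd = attempt("psd", lambda: ensemble.velocity_psd(tracks))
    if psd is not None:
        pd.DataFrame({"freq_cyc_per_min": psd.frequencies, "psd": psd.psd}).to_csv(
            out / "psd.csv", index=False
        )
        try:
            pw = ensemble.fit_psd_piecewise(psd)
            manifest["psd_fit"] = {
                "breakpoint_freq": pw.breakpoint_freq,
                "slope_low": pw.slope_low,
                "slope_high": pw.slope_high,
                "degenerate": pw.degenerate,
            }
        except ValueError as err:
            manifest["skipped"].append({"analysis": "psd_fit", "reason": str(err)})

    bouts = attempt("bouts", lambda: ensemble.bout_distribution(tracks))
    if bouts is not None:
        bouts.to_frame().to_csv(out / "bouts.csv", index=False)
        manifest["bout_fit"] = {
            "A": bouts.A,
            "gamma": bouts.gamma,
            "beta_stretch": bouts.beta_stretch,
            "n_bouts": bouts.n_bouts,
        }

    if "ks" in cfg.analyses:
        ks_rows = []
        for stat in ("speed", "turn_angle"):
            res = attempt("ks", lambda s=stat: ensemble.ks_heterogeneity(tracks, s, cfg.ks_alpha))
            if res is not None:
                res.table.assign(statistic=stat).to_csv(out / f"ks_{stat}.csv", index=False)
                ks_rows.append({"statistic": stat, "fraction_flagged": res.fraction_flagged})
        manifest["ks"] = ks_rows

    classes = attempt(
        "speed_classes",
        lambda: ensemble.speed_class_analysis(
            tracks, cfg.n_classes, n_boot=cfg.n_boot, seed=seeds["speed_classes"]
        ),
    )
    if classes is not None:
        classes.assignments.to_csv(out / "speed_classes.csv", index=False)
        classes.angle_hist.to_csv(out / "speed_class_angles.csv", index=False)
        classes.conditioned_turning.to_csv(out / "speed_class_turning.csv", index=False)

    switching = attempt(
        "switching",
        lambda: ensemble.speed_switching(
            tracks,
            cfg.block_minutes,
            n_perm=cfg.n_perm,
            n_boot=cfg.n_boot,
            seed=seeds["switching"],
        ),
    )
    if switching is not None:
        switching.table.to_csv(out / "switching.csv", index=False)

    coupling = attempt(
        "coupling",
        lambda: diffusion.persistence_vs_speed(
            summaries, cfg.coupling_bins, n_boot=cfg.n_boot, seed=seeds["coupling"]
        ),
    )
    if coupling is not None:
        coupling.bins.to_csv(out / "coupling.csv", index=False)
        manifest["coupling_fit"] = {
            "alpha": coupling.alpha,
            "beta": coupling.beta,
            "slope": coupling.slope,
            "slope_se": coupling.slope_se,
            "upt_consistent": coupling.upt_consistent,
        }

    deff = attempt(
        "deff",
        lambda: diffusion.deff_table(
            tracks,
            taus=cfg.deff_taus,
            bin_frac=cfg.deff_bin_frac,
            n_boot=cfg.n_boot,
            seed=seeds["deff"],
        ),
    )
    if deff is not None:
        deff.table.to_csv(out / "deff.csv", index=False)

    if "scaling" in cfg.analyses and deff is not None and coupling is not None:
        try:
            upt, spc = diffusion.fit_scaling(deff, coupling)
            scaling = {
                f.model: {
                    "constant": f.constant,
                    "rss_log": f.rss_log,
                    "fold_variation": f.fold_variation,
                }
                for f in (upt, spc)
            }
            (out / "scaling.json").write_text(json.dumps(scaling, indent=1))
        except ValueError as err:
            manifest["skipped"].append({"analysis": "scaling", "reason": str(err)})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


@dataclass(frozen=True)
class ConditionComparison:
    """Two-condition comparison of speed distributions and turning curves.

    ``speed_hist``: per-condition density histograms of per-track mean speed
    on shared bins. ``cos_curves``: per-condition mean turn cosine vs speed on
    shared quantile bins with bootstrap CIs. ``overlap_fraction``: fraction of
    bins populated by both conditions whose CIs overlap (1.0 when the turning
    curves coincide within uncertainty, the manifold-preservation signature).
    """

    speed_hist: pd.DataFrame
    cos_curves: pd.DataFrame
    overlap_fraction: float
    median_speeds: dict


def compare_conditions(
    tracks_a: TrajectorySet,
    tracks_b: TrajectorySet,
    labels: tuple[str, str] = ("a", "b"),
    n_bins: int = 8,
    n_boot: int = 1000,
    min_tracks_per_bin: int = 5,
    seed: int | None = None,
) -> ConditionComparison:
    """Compare two track sets: speed distributions vs speed-turning curves.

    Both conditions' per-track mean speeds are histogrammed on shared bins;
    the mean turn cosine is binned on shared speed-quantile bins (quantiles
    of the pooled speeds) with a bootstrap-over-tracks CI per condition, and
    the per-bin CI overlap is reported.
    """
    rng = np.random.default_rng(seed)
    sums = {}
    for label, tracks in zip(labels, (tracks_a, tracks_b)):
        if len(tracks) == 0:
            raise ValueError(f"condition {label!r} has no tracks")
        sums[label] = kinematics.summarize_set(tracks)
    n_bins = max(2, min(n_bins, min(len(s) for s in sums.values()) // min_tracks_per_bin))
    pooled_speeds = np.concatenate([s["mean_speed"].to_numpy() for s in sums.values()])
    hist_edges = np.histogram_bin_edges(pooled_speeds, bins=max(n_bins * 2, 10))
    hist_rows = []
    for label, s in sums.items():
        dens, _ = np.histogram(s["mean_speed"], bins=hist_edges, density=True)
        for j in range(len(dens)):
            hist_rows.append(
                {
                    "condition": label,
                    "speed": 0.5 * (hist_edges[j] + hist_edges[j + 1]),
                    "density": dens[j],
                }
            )
    edges = np.unique(np.quantile(pooled_speeds, np.linspace(0, 1, n_bins + 1)))
    edges[0], edges[-1] = -np.inf, np.inf
    curve_rows = []
    per_bin = {}
    for label, s in sums.items():
        sp = s["mean_speed"].to_numpy()
        mc = s["mean_cos"].to_numpy()
        ok = np.isfinite(mc)
        sp, mc = sp[ok], mc[ok]
        idx = np.clip(np.searchsorted(edges, sp, side="right") - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            m = idx == b
            if m.sum() < min_tracks_per_bin:
                continue
            vals = mc[m]
            boot = np.array(
                [vals[rng.integers(0, len(vals), len(vals))].mean() for _ in range(n_boot)]
            )
            lo, hi = np.percentile(boot, [2.5, 97.5])
            curve_rows.append(
                {
                    "condition": label,
                    "bin": b,
                    "speed": float(sp[m].mean()),
                    "mean_cos": float(vals.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n_tracks": int(m.sum()),
                }
            )
            per_bin.setdefault(b, {})[label] = (lo, hi)
    common = [b for b, d in per_bin.items() if len(d) == 2]
    if common:
        overlaps = [
            per_bin[b][labels[0]][0] <= per_bin[b][labels[1]][1]
            and per_bin[b][labels[1]][0] <= per_bin[b][labels[0]][1]
            for b in common
        ]
        overlap_fraction = float(np.mean(overlaps))
    else:
        overlap_fraction = float("nan")
    return ConditionComparison(
        speed_hist=pd.DataFrame(hist_rows),
        cos_curves=pd.DataFrame(curve_rows),
        overlap_fraction=overlap_fraction,
        median_speeds={
            label: float(np.median(s["mean_speed"])) for label, s in sums.items()
        },
    )
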