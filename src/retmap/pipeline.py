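"""End-to-end orchestration: simulate/load → scenes → state → fits → transitions.

The pipeline is deterministic given a config and seed: every stochastic
stage draws from generators seeded from ``config.seed``, and reports are
serialized with sorted keys so identical runs produce byte-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import preprocessing as prep
from . import returnmap as rm
from . import state as st
from . import synthetic as syn
from . import transitions as tr

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineError",
    "run_pipeline",
    "write_report",
    "report_to_json",
    "make_fixture_suite",
]

log = logging.getLogger("retmap")


class PipelineError(RuntimeError):
    """Stage failure, annotated with stage name and scene/match ids."""


@dataclass
class PipelineConfig:
    """Resolved parameters for one end-to-end run."""

    seed: int = 0
    # --- input: either simulation or CSV paths -------------------------
    simulate: bool = True
    sim_mode: str = "single_aa"  # single_aa | switching | fn_mixture
    n_matches: int = 2
    scenes_per_match: int = 5
    noise_sigma: float = 0.0
    groups: tuple[str, ...] = ("expert", "intermediate")
    # fn_mixture: per-group probability of staying in the high (F) mode
    p_stay_high: dict = field(default_factory=lambda: {"expert": 0.7, "intermediate": 0.45})
    inputs: tuple = ()  # sequence of {"path":…, "group":…, "exclusions":[(s,e),…]}
    # --- preprocessing -------------------------------------------------
    filter_order: int = 4
    filter_cutoff_hz: float | None = 6.0  # None: bypass position filtering
    zero_phase: bool = True
    min_positive_peaks: int = 4
    close_threshold_m: float | None = 0.73
    close_quantile: float = 0.25
    # --- state variable ------------------------------------------------
    tau_s: float = 0.1
    composite_weight: float = 0.5
    # --- return map ----------------------------------------------------
    sg_order: int = 2
    sg_window: int = 9
    min_separation_s: float = 0.0
    sigma: float = rm.DEFAULT_SIGMA
    q_min: float = 0.05
    tie_break: str = "parsimony"
    scene_margin_s: float = 0.5
    # --- transitions ---------------------------------------------------
    bin_width: float = 0.05
    linear_fits_only: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("groups", "inputs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in d[key]
                )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    """Aggregated outputs of one pipeline run."""

    config: PipelineConfig
    fits: pd.DataFrame
    n_scenes: dict[str, int]
    class_by_length: dict[str, dict[str, dict[int, int]]]
    functions_per_scene: dict[str, dict[int, int]]
    transition_models: dict[str, dict[int, tr.TransitionModel]]
    comparisons: dict[int, tr.GroupComparison]
    labeling_failures: list[str]

    def totals(self) -> dict[str, int]:
        """Aggregate fit counts: attractors + repellers + intermittency."""
        counts = {"attractor": 0, "repeller": 0, "intermittency": 0, "total": 0}
        for cls_counts in self.class_by_length.values():
            for cls, by_len in cls_counts.items():
                n = sum(by_len.values())
                counts["total"] += n
                if cls in ("Aa", "Ar"):
                    counts["attractor"] += n
                elif cls in ("Ra", "Rr"):
                    counts["repeller"] += n
                else:
                    counts["intermittency"] += n
        return counts


# ---------------------------------------------------------------------------
# simulation front-ends
# ---------------------------------------------------------------------------


def _scene_spec_single_aa(rng: np.random.Generator, noise_sigma: float, seed: int):
    c = float(rng.uniform(0.4, 0.6))
    start = float(rng.uniform(0.8, 0.95))
    fp = float(rng.uniform(0.3, 0.45))
    reg = syn.RegimeSpec("linear", (c, fp * (1 - c)), 8, initial_peak=start)
    return syn.SyntheticSpec(regimes=(reg,), noise_sigma=noise_sigma, seed=seed)


def _scene_spec_switching(rng: np.random.Generator, noise_sigma: float, seed: int):
    n_regimes = int(rng.integers(2, 5))
    regimes = syn.random_switching_regimes(rng, n_regimes)
    return syn.SyntheticSpec(regimes=tuple(regimes), noise_sigma=noise_sigma, seed=seed)


def _scene_spec_fn(rng: np.random.Generator, noise_sigma: float, seed: int,
                   p_stay_high: float):
    regimes = syn.markov_regime_chain(
        rng, int(rng.integers(3, 5)),
        p_stay_high=p_stay_high, p_stay_low=1.0 - p_stay_high,
        start_high=bool(rng.random() < 0.5),
    )
    return syn.SyntheticSpec(regimes=tuple(regimes), noise_sigma=noise_sigma, seed=seed)


def _simulate_matches(config: PipelineConfig):
    matches = []
    for g_idx, group in enumerate(config.groups):
        for m in range(config.n_matches):
            seed = config.seed * 100_003 + g_idx * 1_009 + m
            rng = np.random.default_rng(seed)
            specs = []
            for s in range(config.scenes_per_match):
                if config.sim_mode == "single_aa":
                    spec = _scene_spec_single_aa(rng, config.noise_sigma, seed + s)
                elif config.sim_mode == "switching":
                    spec = _scene_spec_switching(rng, config.noise_sigma, seed + s)
                elif config.sim_mode == "fn_mixture":
                    spec = _scene_spec_fn(rng, config.noise_sigma, seed + s,
                                          config.p_stay_high[group])
                else:
                    raise ValueError(f"unknown sim_mode {config.sim_mode!r}")
                specs.append(spec)
            traj, truth = syn.generate_match(
                specs, match_id=f"{group}_{m:02d}", group=group
            )
            matches.append((traj, (), truth))
    return matches


def _load_matches(config: PipelineConfig):
    matches = []
    for item in config.inputs:
        path = Path(item["path"])
        if not path.exists():
            raise PipelineError(f"input trajectory not found: {path}")
        traj = prep.TrajectoryPair.from_csv(
            path, match_id=item.get("match_id", path.stem),
            group=item.get("group", ""),
        )
        exclusions = tuple(tuple(x) for x in item.get("exclusions", ()))
        matches.append((traj, exclusions, None))
    return matches


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def _analyze_match(traj, exclusions, config: PipelineConfig):
    """One match: filter → IPD → scenes → state → per-scene segmentation."""
    if config.filter_cutoff_hz is not None:
        traj = prep.lowpass_positions(
            traj, order=config.filter_order, cutoff_hz=config.filter_cutoff_hz,
            zero_phase=config.zero_phase,
        )
    ipd = prep.compute_ipd(traj, filtered=config.filter_cutoff_hz is not None)
    scenes = prep.split_scenes(
        ipd, exclusions,
        min_positive_peaks=config.min_positive_peaks,
        close_quantile=config.close_quantile,
        close_threshold_m=config.close_threshold_m,
    )
    state = st.build_state_series(ipd, tau=config.tau_s, weight=config.composite_weight)
    margin = int(round(config.scene_margin_s / ipd.dt))
    results = []
    for scene in scenes:
        lo = max(state.valid_from, scene.start - margin)
        s_slice = state.s[lo : scene.stop]
        t_slice = state.time[lo : scene.stop]
        try:
            smoothed = rm.smooth_sg(s_slice, order=config.sg_order,
                                    window=config.sg_window)
            peaks = rm.detect_peaks(
                smoothed, t_slice, min_separation_s=config.min_separation_s,
                scene_id=scene.scene_id,
            )
            if len(peaks) < 2:
                continue
            points = rm.build_return_map(peaks)
            if points.shape[0] < min(rm.WINDOW_LENGTHS):
                continue
            seg = rm.analyze_points(
                points, sigma=config.sigma, q_min=config.q_min,
                tie_break=config.tie_break, scene_id=scene.scene_id,
            )
        except (ValueError, rm.FitError) as exc:
            raise PipelineError(
                f"return-map stage failed for match {traj.match_id} "
                f"scene {scene.scene_id}: {exc}"
            ) from exc
        results.append((scene, peaks, seg))
    return ipd, scenes, results


def _fitted_peak_labels(results, config: PipelineConfig, match_id: str):
    """Histogram → threshold → scene-ordered F/N labels of well-fitted peaks."""
    scene_values: list[list[float]] = []
    for _scene, peaks, seg in results:
        vals: list[float] = []
        seen: set[int] = set()
        for fit in seg.fits:
            if config.linear_fits_only and fit.family != "linear":
                continue
            for p in range(fit.start, fit.stop + 1):  # window points ↔ L+1 peaks
                if p not in seen:
                    seen.add(p)
                    vals.append(float(peaks.amplitudes[p]))
        scene_values.append(vals)
    all_vals = [v for vals in scene_values for v in vals]
    counts, edges = tr.peak_histogram(all_vals, bin_width=config.bin_width)
    threshold = tr.find_threshold(counts, edges)
    labels = [tr.label_states(vals, threshold) for vals in scene_values]
    return tr.StateLabeling(
        match_id=match_id, threshold=threshold, scene_labels=labels,
        bin_edges=edges, counts=counts,
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and aggregate the report."""
    matches = _simulate_matches(config) if config.simulate else _load_matches(config)

    rows = []
    n_scenes: dict[str, int] = {}
    class_by_length: dict[str, dict[str, dict[int, int]]] = {}
    functions_per_scene: dict[str, dict[int, int]] = {}
    labelings: dict[str, list[tr.StateLabeling]] = {}
    labeling_failures: list[str] = []

    for traj, exclusions, _truth in matches:
        group = traj.group
        _ipd, scenes, results = _analyze_match(traj, exclusions, config)
        n_scenes[group] = n_scenes.get(group, 0) + len(scenes)
        log.info("match %s: %d scenes, %d analyzed", traj.match_id,
                 len(scenes), len(results))
        for scene, _peaks, seg in results:
            fps = functions_per_scene.setdefault(group, {})
            fps[seg.n_functions] = fps.get(seg.n_functions, 0) + 1
            for fit in seg.fits:
                cls = fit.cls or "degenerate"
                cbl = class_by_length.setdefault(group, {})
                by_len = cbl.setdefault(cls, {})
                by_len[fit.length] = by_len.get(fit.length, 0) + 1
                rows.append(
                    {
                        "match_id": traj.match_id,
                        "group": group,
                        "scene_id": scene.scene_id,
                        "start": fit.start,
                        "length": fit.length,
                        "family": fit.family,
                        "class": cls,
                        "param_0": fit.params[0],
                        "param_1": fit.params[1],
                        "chi2": fit.chi2,
                        "q": fit.q,
                        "fixed_point": fit.fixed_point,
                    }
                )
        try:
            labeling = _fitted_peak_labels(results, config, traj.match_id)
            labelings.setdefault(group, []).append(labeling)
        except tr.ThresholdError as exc:
            labeling_failures.append(f"{traj.match_id}: {exc}")

    transition_models: dict[str, dict[int, tr.TransitionModel]] = {}
    for group, labs in labelings.items():
        try:
            transition_models[group] = {
                2: tr.second_order(labs, group=group),
                3: tr.third_order(labs, group=group),
            }
        except ValueError as exc:
            labeling_failures.append(f"group {group}: {exc}")

    comparisons: dict[int, tr.GroupComparison] = {}
    groups_with_models = sorted(transition_models)
    if len(groups_with_models) == 2:
        ga, gb = groups_with_models
        for order in (2, 3):
            comparisons[order] = tr.fisher_compare(
                transition_models[ga][order], transition_models[gb][order]
            )

    fits_df = pd.DataFrame(
        rows,
        columns=[
            "match_id", "group", "scene_id", "start", "length", "family",
            "class", "param_0", "param_1", "chi2", "q", "fixed_point",
        ],
    )
    return RunReport(
        config=config,
        fits=fits_df,
        n_scenes=n_scenes,
        class_by_length=class_by_length,
        functions_per_scene=functions_per_scene,
        transition_models=transition_models,
        comparisons=comparisons,
        labeling_failures=labeling_failures,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def report_to_json(report: RunReport) -> str:
    """Deterministic JSON rendering (sorted keys, repr floats)."""
    payload = {
        "config": report.config.to_dict(),
        "n_scenes": report.n_scenes,
        "totals": report.totals(),
        "class_by_length": report.class_by_length,
        "functions_per_scene": report.functions_per_scene,
        "transition_models": {
            g: {
                order: {"counts": m.counts, "probs": m.probs}
                for order, m in models.items()
            }
            for g, models in report.transition_models.items()
        },
        "comparisons": {
            order: {
                "groups": [c.group_a, c.group_b],
                "tables": {k: v.tolist() for k, v in c.tables.items()},
                "pvalues": c.pvalues,
            }
            for order, c in report.comparisons.items()
        },
        "labeling_failures": report.labeling_failures,
        "fits": report.fits.to_dict(orient="records"),
    }
    return json.dumps(_jsonify(payload), sort_keys=True, indent=1)


def write_report(report: RunReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report_to_json(report))
    report.fits.to_csv(outdir / "fits.csv", index=False, float_format="%.9g")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(report.config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

_FIXTURE_REGIMES = {
    "fig3_Aa": syn.RegimeSpec("linear", (0.5, 0.3), 8, initial_peak=0.95),
    "fig3_Ar": syn.RegimeSpec("linear", (-0.5, 0.9), 8, initial_peak=0.9),
    "fig3_Ra": syn.RegimeSpec("linear", (1.3, -0.15), 7, initial_peak=0.55),
    "fig3_Rr": syn.RegimeSpec("linear", (-1.3, 1.15), 7, initial_peak=0.55),
    "fig3_Exp": syn.RegimeSpec("exponential", (0.16, 2.5), 8, initial_peak=0.25),
    "fig3_Log": syn.RegimeSpec(
        "logarithmic", (0.45 - 0.4 * np.log(0.45), 0.4), 8, initial_peak=0.9
    ),
}


def make_fixture_suite(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write the canonical small test inputs; byte-identical per seed.

    One single-regime match per function class, one three-regime switching
    scene (attractor → repeller → attractor), and a two-group match set
    with different planted F/N chains for the group comparison.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, specs, group: str = "fixture"):
        traj, truth = syn.generate_match(specs, match_id=name, group=group)
        path = outdir / f"{name}.csv"
        traj.to_csv(path)
        meta = {
            "scenes": [
                {
                    "clean_peaks": t.clean_peaks.tolist(),
                    "families": t.families,
                    "fixed_points": t.fixed_points,
                    "regime_of_peak": t.regime_of_peak.tolist(),
                    "fn_labels": t.fn_labels,
                }
                for t in truth.scenes
            ],
            "scene_sample_ranges": truth.scene_sample_ranges,
        }
        (outdir / f"{name}.truth.json").write_text(
            json.dumps(_jsonify(meta), sort_keys=True, indent=1)
        )
        written[name] = path

    for name, regime in _FIXTURE_REGIMES.items():
        emit(name, syn.SyntheticSpec(regimes=(regime,), seed=seed))

    switch = (
        syn.RegimeSpec("linear", (0.5, 0.35), 5, initial_peak=0.95),
        syn.RegimeSpec("linear", (-1.35, 1.55), 4),
        syn.RegimeSpec("linear", (0.45, 0.22), 5),
    )
    emit("fig4_switch3", syn.SyntheticSpec(regimes=switch, seed=seed + 1))

    rng = np.random.default_rng(seed + 2)
    for group, p_stay in (("expert", 0.7), ("intermediate", 0.45)):
        for m in range(2):
            specs = []
            for s in range(6):
                regimes = syn.markov_regime_chain(
                    rng, 4, p_stay_high=p_stay, p_stay_low=1.0 - p_stay,
                    start_high=bool(rng.random() < 0.5),
                )
                specs.append(
                    syn.SyntheticSpec(
                        regimes=tuple(regimes),
                        seed=seed + 10 + m,
                        noise_sigma=0.01,
                    )
                )
            emit(f"twogroup_{group}_{m}", specs, group=group)
    return written
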