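"""End-to-end orchestration: simulate -> connect -> analyze.

Each stage reads and writes plain-text artifacts (CSV/JSON) under the
configured output directory, tags every file with the config hash and seed
that produced it, and is deterministic given both.  ``connect`` is
resumable: existing association matrices with valid checksums are skipped
unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import graphs, stats
from .config import PipelineConfig
from .connectivity import MIMatrix, association_matrix
from .preprocess import detrend_linear, downsample, extract_epochs, morlet_band_series
from .signals import Band, MultichannelRecording
from .simulate import (
    CONDITIONS,
    SimulationConfig,
    TopologyConfig,
    null_strengths,
    planted_interaction_strengths,
    simulate_cohort,
)

__all__ = ["ConfigError", "DataError", "run_simulate", "run_connect", "run_analyze", "run_report"]

logger = logging.getLogger("econets.pipeline")


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or corrupted data (CLI exit code 3)."""


def _tag(config: PipelineConfig) -> str:
    return f"config={config.config_hash()} seed={config.seed}"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_checksum(path: Path) -> None:
    path.with_suffix(path.suffix + ".sha256").write_text(_sha256(path) + "\n")


def _checksum_ok(path: Path) -> bool:
    sidecar = path.with_suffix(path.suffix + ".sha256")
    if not path.exists() or not sidecar.exists():
        return False
    return _sha256(path) == sidecar.read_text().strip()


def _bands(config: PipelineConfig) -> tuple[Band, ...]:
    return tuple(Band(name, lo, hi) for name, (lo, hi) in config.bands.items())


def simulation_config(config: PipelineConfig) -> SimulationConfig:
    sim = config.simulation
    if sim.preset == "planted":
        strengths = planted_interaction_strengths()
    elif sim.preset == "null":
        strengths = null_strengths(sim.null_level)
    else:
        raise ConfigError(f"unknown simulation preset {sim.preset!r}")
    return SimulationConfig(
        n_channels=sim.n_channels,
        fs=sim.fs,
        epoch_len=sim.epoch_len,
        n_epochs=sim.n_epochs,
        n_per_group=sim.n_per_group,
        bands=_bands(config),
        topology=TopologyConfig(model=sim.topology_model, cost=sim.topology_cost, rewire_p=sim.rewire_p),
        coupling_strength=strengths,
        lattice_strength=sim.lattice_strength,
        duration_slope=sim.duration_slope,
        duration_range=sim.duration_range,
        noise_sd=sim.noise_sd,
        seed=config.seed,
    )


def cohort_metric_table(
    cohort,
    epoch_len: float,
    bands=None,
    costs=(0.3,),
    metrics=("Eglob",),
    n_bins: int = 16,
    omega0: float = 6.0,
    voices_per_octave: int = 4,
) -> pd.DataFrame:
    """In-memory cohort -> tidy metric table (no disk round-trip).

    Runs the preprocessing + connectivity + graph-metric chain on every
    recording of a :class:`~econets.simulate.CohortDataset` and returns one
    row per (subject, condition, band, cost, metric).  The disk-based
    ``connect``/``analyze`` stages produce the same numbers; this helper is
    the convenient path for simulation studies.
    """
    from .signals import DEFAULT_BANDS

    bands = bands if bands is not None else DEFAULT_BANDS
    group_of = {r.id: r.group for r in cohort.manifest}
    rows = []
    for (sid, cond), rec in sorted(cohort.recordings.items()):
        n_ep = int(rec.duration // epoch_len + 1e-9)
        epochs = detrend_linear(extract_epochs(rec, n_ep, epoch_len))
        for band in bands:
            series = morlet_band_series(
                epochs, band, omega0=omega0, voices_per_octave=voices_per_octave
            )
            mi = association_matrix(series, n_bins=n_bins, subject_id=sid, condition=cond)
            for c in costs:
                g = graphs.threshold_by_cost(mi, float(c))
                values = {}
                if "Eglob" in metrics or "CE" in metrics:
                    values["Eglob"] = graphs.global_efficiency(g)
                if "CE" in metrics:
                    values["CE"] = values["Eglob"] - float(c)
                if "Elocal" in metrics:
                    values["Elocal"] = graphs.local_efficiency(g)
                for name in metrics:
                    rows.append(
                        {"subject": sid, "group": group_of[sid], "condition": cond,
                         "band": band.name, "cost": float(c), "metric": name,
                         "value": float(values[name])}
                    )
    return pd.DataFrame(rows)


def run_simulate(config: PipelineConfig) -> Path:
    """Generate the synthetic cohort and write it under ``output_dir/recordings``."""
    t0 = time.time()
    outdir = Path(config.output_dir) / "recordings"
    cohort = simulate_cohort(simulation_config(config))
    manifest = cohort.write(outdir)
    (outdir / "run_tag.json").write_text(
        json.dumps({"stage": "simulate", "tag": _tag(config)}, indent=1)
    )
    logger.info(
        "simulate: %d subjects, %d recordings -> %s (%.1f s, %s)",
        len(cohort.manifest), len(manifest), outdir, time.time() - t0, _tag(config),
    )
    return outdir / "manifest.csv"


def _load_manifest(config: PipelineConfig) -> tuple[pd.DataFrame, Path]:
    if config.input_manifest is not None:
        manifest_path = Path(config.input_manifest)
    else:
        manifest_path = Path(config.output_dir) / "recordings" / "manifest.csv"
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path} (run the simulate stage first?)")
    return pd.read_csv(manifest_path), manifest_path.parent


def run_connect(config: PipelineConfig, force: bool = False) -> Path:
    """Preprocess every recording and write one MI matrix per band."""
    t0 = time.time()
    manifest, recdir = _load_manifest(config)
    midir = Path(config.output_dir) / "mi"
    midir.mkdir(parents=True, exist_ok=True)
    bands = _bands(config)

    missing = [row.path for row in manifest.itertuples() if not (recdir / row.path).exists()]
    if missing:
        raise DataError(f"missing recordings: {missing}")

    n_done = n_skipped = 0
    for row in manifest.itertuples():
        targets = {b.name: midir / f"{row.id}_{row.condition}_{b.name}.csv" for b in bands}
        fresh = {name: _checksum_ok(p) for name, p in targets.items()}
        stale = [p for name, p in targets.items() if not fresh[name] and p.exists()]
        if stale and not force:
            raise DataError(f"checksum failure (corrupted output?): {stale}")
        if all(fresh.values()) and not force:
            logger.info("connect: %s %s skipped (up to date)", row.id, row.condition)
            n_skipped += 1
            continue
        rec = MultichannelRecording.from_csv(recdir / row.path, fs=row.fs)
        rec = downsample(rec, config.downsample_factor)
        # epoch length: every recording carries an integer number of epochs
        sim = config.simulation
        epochs = extract_epochs(rec, int(rec.duration // sim.epoch_len), sim.epoch_len)
        epochs = detrend_linear(epochs)
        for band in bands:
            series = morlet_band_series(
                epochs, band, omega0=config.wavelet.omega0,
                voices_per_octave=config.wavelet.voices_per_octave,
                mode=config.wavelet.mode,
            )
            mi = association_matrix(
                series, n_bins=config.mi.n_bins, per_epoch=config.mi.per_epoch,
                subject_id=str(row.id), condition=str(row.condition),
            )
            mi.to_csv(targets[band.name], header_comment=_tag(config))
            _write_checksum(targets[band.name])
        n_done += 1
    logger.info(
        "connect: %d computed, %d skipped (%.1f s, %s)",
        n_done, n_skipped, time.time() - t0, _tag(config),
    )
    return midir


def _null_cache(n: int, costs: np.ndarray, n_draws: int, seed: int) -> dict[float, graphs.NullEnsemble]:
    cache: dict[float, graphs.NullEnsemble] = {}
    npairs = n * (n - 1) // 2
    for c in costs:
        m = int(round(float(c) * npairs))
        cache[float(c)] = graphs.build_null_ensemble(n, m, n_draws=n_draws, seed=seed + int(round(c * 1000)))
    return cache


def run_analyze(config: PipelineConfig) -> Path:
    """Curves, small-world regimes, and the full cohort statistics reports."""
    t0 = time.time()
    manifest, _ = _load_manifest(config)
    midir = Path(config.output_dir) / "mi"
    outdir = Path(config.output_dir) / "analysis"
    outdir.mkdir(parents=True, exist_ok=True)
    bands = _bands(config)
    grid = graphs.default_cost_grid(config.cost_grid.start, config.cost_grid.stop, config.cost_grid.step)
    analysis_cost = config.statistics.analysis_cost
    if not np.isclose(grid, analysis_cost).any():
        analysis_cost = float(grid[len(grid) // 2])
        logger.warning("analysis cost not on grid; using mid-grid cost %.2f", analysis_cost)
    tag = _tag(config)

    cols = ["id", "group", "condition", "duration_years"]
    if "age" in manifest.columns:
        cols.append("age")
    meta = manifest[cols].astype({"id": str})
    subjects = meta.drop(columns="condition").drop_duplicates("id")

    curve_rows = []
    nodal_rows = []
    maxce_rows = []
    nulls: dict[float, graphs.NullEnsemble] | None = None
    n_channels = None
    for row in meta.itertuples():
        for band in bands:
            path = midir / f"{row.id}_{row.condition}_{band.name}.csv"
            if not path.exists():
                raise DataError(f"missing MI matrix: {path} (run the connect stage first?)")
            if not _checksum_ok(path):
                raise DataError(f"checksum failure (corrupted MI matrix?): {path}")
            mi = MIMatrix.from_csv(path, band=band, subject_id=row.id, condition=row.condition)
            if n_channels is None:
                n_channels = mi.n_channels
                nulls = _null_cache(n_channels, grid, config.null_draws, config.seed)
            curves = graphs.metric_curves(mi, grid, subject_id=row.id, condition=row.condition, band=band.name)
            for name in ("Eglob", "Elocal", "CE", "Cp", "Lp"):
                for c, v in zip(grid, curves[name].values):
                    curve_rows.append(
                        {"subject": row.id, "group": row.group, "condition": row.condition,
                         "band": band.name, "cost": float(c), "metric": name, "value": float(v)}
                    )
            _, maxce, argmax_cost = graphs.cost_efficiency_curve(curves["Eglob"])
            maxce_rows.append(
                {"subject": row.id, "group": row.group, "condition": row.condition,
                 "band": band.name, "metric": "maxCE", "value": maxce, "argmax_cost": argmax_cost}
            )
            g = graphs.threshold_by_cost(mi, analysis_cost)
            enodal = graphs.nodal_efficiency(g)
            degree = g.degrees.astype(float)
            labels = mi.labels or tuple(f"ch{i}" for i in range(mi.n_channels))
            for node, (dv, ev) in enumerate(zip(degree, enodal)):
                nodal_rows.append(
                    {"subject": row.id, "group": row.group, "condition": row.condition,
                     "band": band.name, "node": labels[node], "degree": dv, "Enodal": ev}
                )

    curve_table = pd.DataFrame(curve_rows)
    with open(outdir / "curves.csv", "w") as fh:
        fh.write(f"# {tag}\n")
        curve_table.to_csv(fh, index=False)
    maxce_table = pd.DataFrame(maxce_rows)

    # small-world regime per band from group-mean curves (pooled over groups/conditions)
    regimes = {}
    for band in bands:
        sub = curve_table[curve_table["band"] == band.name]
        mean_eg = sub[sub["metric"] == "Eglob"].groupby("cost")["value"].mean()
        mean_el = sub[sub["metric"] == "Elocal"].groupby("cost")["value"].mean()
        eg_curve = graphs.MetricCurve("Eglob", grid, mean_eg.loc[grid].to_numpy(), band=band.name)
        el_curve = graphs.MetricCurve("Elocal", grid, mean_el.loc[grid].to_numpy(), band=band.name)
        regime = graphs.small_world_regime(eg_curve, el_curve, [nulls[float(c)] for c in grid], band=band.name)
        regimes[band.name] = {
            "valid": regime.valid,
            "excluded": not regime.valid,
            "c_low": None if not regime.valid else regime.c_low,
            "c_high": None if not regime.valid else regime.c_high,
        }
    (outdir / "regimes.json").write_text(json.dumps({"tag": tag, "bands": regimes}, indent=1))
    valid_bands = [b.name for b in bands if regimes[b.name]["valid"]]
    if not valid_bands:
        warnings.warn("no band shows a valid small-world regime; statistics are skipped")

    # per-cost ANOVA scan on the global metrics, for bands with a valid regime
    anova_rows = []
    cell_keys = [("patient", "rest"), ("patient", "task"), ("control", "rest"), ("control", "task")]
    for band_name in valid_bands:
        for metric in ("Eglob", "Elocal", "CE"):
            for c in grid:
                sub = curve_table[
                    (curve_table["band"] == band_name)
                    & (curve_table["metric"] == metric)
                    & np.isclose(curve_table["cost"], float(c))
                ]
                results = stats.anova_2x2(sub, mode=config.statistics.mode)
                cells = {}
                for gname, cname in cell_keys:
                    vals = sub[(sub["group"] == gname) & (sub["condition"] == cname)]["value"]
                    cells[f"mean_{gname}_{cname}"] = float(vals.mean())
                    cells[f"sem_{gname}_{cname}"] = float(vals.sem(ddof=1)) if len(vals) > 1 else np.nan
                for res in results:
                    anova_rows.append(
                        {"band": band_name, "metric": metric, "cost": float(c),
                         "effect": res.effect, "F": res.F, "df_num": res.df[0],
                         "df_den": res.df[1], "p": res.p, **cells}
                    )
            # maxCE is a single per-subject scalar, analyzed once per band/metric
        sub = maxce_table[maxce_table["band"] == band_name]
        for res in stats.anova_2x2(sub, mode=config.statistics.mode):
            anova_rows.append(
                {"band": band_name, "metric": "maxCE", "cost": np.nan, "effect": res.effect,
                 "F": res.F, "df_num": res.df[0], "df_den": res.df[1], "p": res.p}
            )
    anova_table = pd.DataFrame(anova_rows)
    with open(outdir / "anova_per_cost.csv", "w") as fh:
        fh.write(f"# {tag}\n")
        anova_table.to_csv(fh, index=False)

    # post-hoc t-tests at the analysis cost
    posthoc_frames = []
    for band_name in valid_bands:
        for metric in ("Eglob", "Elocal", "CE"):
            sub = curve_table[
                (curve_table["band"] == band_name)
                & (curve_table["metric"] == metric)
                & np.isclose(curve_table["cost"], analysis_cost)
            ]
            ph = stats.posthoc_ttests(sub)
            ph.insert(0, "band", band_name)
            ph.insert(1, "metric", metric)
            posthoc_frames.append(ph)
    if posthoc_frames:
        posthoc = pd.concat(posthoc_frames, ignore_index=True)
        with open(outdir / "posthoc.csv", "w") as fh:
            fh.write(f"# {tag}\n")
            posthoc.to_csv(fh, index=False)

    # tiered nodal maps (degree and Enodal at the analysis cost)
    nodal_table = pd.DataFrame(nodal_rows)
    nodal_out = []
    for band_name in valid_bands:
        for metric in ("degree", "Enodal"):
            sub = nodal_table[nodal_table["band"] == band_name][
                ["subject", "group", "condition", "node", metric]
            ].rename(columns={metric: "value"})
            res = stats.nodal_tests(sub)
            res.insert(0, "band", band_name)
            res.insert(1, "metric", metric)
            nodal_out.append(res)
    if nodal_out:
        nodal_res = pd.concat(nodal_out, ignore_index=True)
        with open(outdir / "nodal_tests.csv", "w") as fh:
            fh.write(f"# {tag}\n")
            nodal_res.to_csv(fh, index=False)

    # duration-of-disease correlations (patients only); optionally age as a
    # negative control
    def _correlation_table(covariate: pd.Series) -> pd.DataFrame | None:
        frames = []
        for band_name in valid_bands:
            for metric in ("Eglob", "Elocal", "CE"):
                sub = curve_table[
                    (curve_table["band"] == band_name)
                    & (curve_table["metric"] == metric)
                    & (curve_table["group"] == "patient")
                ]
                corr = stats.duration_correlation(sub, covariate)
                corr.insert(0, "band", band_name)
                corr.insert(1, "metric", metric)
                frames.append(corr)
            sub = maxce_table[(maxce_table["band"] == band_name) & (maxce_table["group"] == "patient")]
            corr = stats.duration_correlation(sub.assign(cost=np.nan), covariate)
            corr.insert(0, "band", band_name)
            corr.insert(1, "metric", "maxCE")
            frames.append(corr)
        if not frames:
            return None
        tidy = pd.concat(frames, ignore_index=True)
        # one row per (band, metric, cost) with R/p columns per condition;
        # cost-free scalars (maxCE) use a sentinel through the pivot
        tidy["cost"] = tidy["cost"].fillna(-1.0)
        wide = tidy.pivot_table(
            index=["band", "metric", "cost"], columns="condition", values=["R", "p"]
        )
        wide.columns = [f"{stat}_{cond}" for stat, cond in wide.columns]
        wide = wide.reset_index()
        wide["cost"] = wide["cost"].replace(-1.0, np.nan)
        return wide

    def _write_corr(name: str, covariate: pd.Series) -> None:
        table = _correlation_table(covariate)
        if table is not None:
            with open(outdir / name, "w") as fh:
                fh.write(f"# {tag}\n")
                table.to_csv(fh, index=False)

    patients = subjects[subjects["group"] == "patient"].set_index("id")
    durations = patients["duration_years"]
    if durations.notna().sum() >= 3:
        _write_corr("duration_correlations.csv", durations)
        if config.statistics.correlate_age and "age" in patients.columns:
            _write_corr("age_correlations.csv", patients["age"])

    # run summary: cost of the most significant interaction per band
    summary: dict = {"tag": tag, "seed": config.seed, "analysis_cost": analysis_cost,
                     "regimes": regimes, "interaction_scan": {}}
    for band_name in valid_bands:
        scan = anova_table[
            (anova_table["band"] == band_name)
            & (anova_table["metric"] == "Eglob")
            & (anova_table["effect"] == "interaction")
            & anova_table["cost"].notna()
        ]
        if not scan.empty:
            best = scan.loc[scan["p"].idxmin()]
            summary["interaction_scan"][band_name] = {
                "cost": float(best["cost"]), "F": float(best["F"]), "p": float(best["p"]),
            }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("analyze: %d bands valid (%.1f s, %s)", len(valid_bands), time.time() - t0, tag)
    return outdir


def run_report(config: PipelineConfig) -> str:
    """Human-readable digest of an analyze run."""
    outdir = Path(config.output_dir) / "analysis"
    summary_path = outdir / "run_summary.json"
    if not summary_path.exists():
        raise DataError(f"no run summary at {summary_path} (run the analyze stage first?)")
    summary = json.loads(summary_path.read_text())
    lines = [f"econets run {summary['tag']}"]
    for band, regime in summary["regimes"].items():
        if regime["valid"]:
            lines.append(
                f"  {band}: small-world regime {regime['c_low']:.2f}..{regime['c_high']:.2f}"
            )
        else:
            lines.append(f"  {band}: no valid small-world regime (excluded)")
    for band, scan in summary["interaction_scan"].items():
        lines.append(
            f"  {band}: strongest Eglob interaction at cost {scan['cost']:.2f} "
            f"(F={scan['F']:.2f}, p={scan['p']:.4f})"
        )
    return "\n".join(lines)
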