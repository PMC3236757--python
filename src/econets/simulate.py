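"""Synthetic EEG-like cohorts with known band-limited coupling structure.

The study design being emulated: two groups (patients, controls) x two
conditions (rest, task), 15 subjects per group, 58 channels sampled at
500 Hz, five 10-s epochs per subject and condition.  Channels are
band-limited AR(2) oscillators (peak at the band center) linearly mixed
along the edges of a planted coupling graph, plus white sensor noise.

The planted effects live in the beta band: a Watts-Strogatz coupling
topology is split into its ring-lattice backbone and its rewired long-range
"shortcut" edges; backbone coupling is fixed, while shortcut coupling
carries a group x condition interaction (controls task > rest, patients
task < rest under the planted-interaction preset) and, for patients, a
signed linear dependence on duration of disease.  Stronger shortcut
coupling makes the recovered thresholded graph more integrated (higher
global efficiency), so the planted effect directions propagate to the
efficiency metrics downstream.

One master seed expands into per-subject/condition streams through
``numpy.random.SeedSequence`` spawn keys, so cohorts are reproducible
subject by subject.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .graphs import (
    AdjacencyGraph,
    random_graph_matched,
    regular_lattice_matched,
    watts_strogatz_matched,
)
from .signals import Band, DEFAULT_BANDS, MultichannelRecording

__all__ = [
    "TopologyConfig",
    "SimulationConfig",
    "SubjectRecord",
    "CohortDataset",
    "planted_interaction_strengths",
    "null_strengths",
    "simulate_coupled_recording",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("rest", "task")


def planted_interaction_strengths() -> dict[str, float]:
    """Effect-band shortcut coupling per group:condition cell.

    Controls gain long-range coupling during the task, patients lose it —
    a pure crossover interaction with no main effects at the cell level.
    """
    return {
        "control:rest": 0.7,
        "control:task": 1.3,
        "patient:rest": 1.3,
        "patient:task": 0.7,
    }


def null_strengths(level: float = 1.0) -> dict[str, float]:
    """All four cells equal: no group, condition or interaction effect."""
    return {f"{g}:{c}": level for g in ("control", "patient") for c in CONDITIONS}


@dataclass
class TopologyConfig:
    """Planted coupling graph: Watts-Strogatz by default."""

    model: str = "ws"  # ws | random | regular
    cost: float = 0.16
    rewire_p: float = 0.2

    def __post_init__(self) -> None:
        if self.model not in ("ws", "random", "regular"):
            raise ValueError(f"unknown topology model {self.model!r}")
        if not (0 < self.cost < 1):
            raise ValueError("topology cost must be in (0, 1)")
        if not (0 <= self.rewire_p <= 1):
            raise ValueError("rewire probability must be in [0, 1]")


@dataclass
class SimulationConfig:
    n_channels: int = 58
    fs: float = 500.0
    epoch_len: float = 10.0
    n_epochs: int = 5
    n_per_group: int = 15
    bands: tuple[Band, ...] = DEFAULT_BANDS
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    #: shortcut coupling of the effect band, per "group:condition" cell
    coupling_strength: dict[str, float] = field(default_factory=planted_interaction_strengths)
    #: uniform coupling of the non-effect bands, per band name (absent -> 0)
    background_strengths: dict[str, float] = field(
        default_factory=lambda: {"alpha": 1.0, "gamma": 0.0}
    )
    #: fixed coupling of the effect band's ring-lattice backbone
    lattice_strength: float = 1.2
    effect_band: str = "beta"
    #: per-year change of patient effect-band shortcut coupling
    duration_slope: float = -0.02
    duration_range: tuple[float, float] = (2.0, 25.0)
    age_range: tuple[float, float] = (40.0, 65.0)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        n_samp = self.epoch_len * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_len x fs must be an integer sample count")
        for key, v in self.coupling_strength.items():
            if v < 0:
                raise ValueError(f"coupling strength for {key} must be >= 0")
        for key, v in self.background_strengths.items():
            if v < 0:
                raise ValueError(f"background strength for {key} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        names = [b.name for b in self.bands]
        if self.effect_band not in names:
            raise ValueError(f"effect band {self.effect_band!r} not among bands {names}")

    @property
    def samples_per_recording(self) -> int:
        return int(round(self.n_epochs * self.epoch_len * self.fs))


@dataclass
class SubjectRecord:
    id: str
    group: str  # patient | control
    age: float
    duration_years: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        has_duration = self.duration_years is not None
        if has_duration != (self.group == "patient"):
            raise ValueError("duration_years must be present iff group == 'patient'")
        if has_duration and self.duration_years < 0:
            raise ValueError("duration must be nonnegative")


@dataclass
class CohortDataset:
    recordings: dict[tuple[str, str], MultichannelRecording]
    manifest: list[SubjectRecord]
    ground_truth: dict

    def __post_init__(self) -> None:
        for rec in self.manifest:
            for cond in CONDITIONS:
                if (rec.id, cond) not in self.recordings:
                    raise ValueError(f"missing recording for {rec.id!r}/{cond!r}")

    @property
    def subjects(self) -> list[str]:
        return [r.id for r in self.manifest]

    def write(self, outdir: str | Path) -> pd.DataFrame:
        """Write delimited recordings + manifest CSV + ground-truth JSON.

        Recording files have rows = samples and columns = channels with a
        header row of channel labels.  Returns the manifest table including
        file paths.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for rec in self.manifest:
            for cond in CONDITIONS:
                fname = f"{rec.id}_{cond}.csv"
                self.recordings[(rec.id, cond)].to_csv(outdir / fname)
                rows.append(
                    {
                        "id": rec.id,
                        "group": rec.group,
                        "condition": cond,
                        "duration_years": rec.duration_years,
                        "age": rec.age,
                        "path": fname,
                        "fs": self.recordings[(rec.id, cond)].fs,
                    }
                )
        manifest = pd.DataFrame(rows)
        manifest.to_csv(outdir / "manifest.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1)
        return manifest


def _ar2_coefficients(band: Band, fs: float) -> tuple[float, float]:
    """AR(2) poles tuned so the spectral peak sits at the band center.

    The pole radius is set from the band half-width so the oscillation
    decorrelates on roughly the band's own timescale.
    """
    f0 = band.center
    bw = band.high - band.low
    r = float(np.exp(-np.pi * bw / (2.0 * fs)))
    r = min(max(r, 0.5), 0.995)
    a1 = 2.0 * r * np.cos(2.0 * np.pi * f0 / fs)
    a2 = -(r**2)
    return a1, a2


def _ar2_sources(
    n_series: int, n_samples: int, band: Band, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance narrowband AR(2) series, one per row."""
    a1, a2 = _ar2_coefficients(band, fs)
    burn = 500
    w = rng.standard_normal((n_series, n_samples + burn))
    x = scipy.signal.lfilter([1.0], [1.0, -a1, -a2], w, axis=-1)[:, burn:]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _coupled_band_signal(
    strengths: np.ndarray, band: Band, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Mix per-channel AR(2) sources along a weighted coupling matrix.

    ``strengths`` is a symmetric nonnegative matrix of per-edge coupling
    coefficients (zero = no edge).  Channel i receives its own source plus a
    degree-normalized weighted sum of its neighbors' sources, which induces
    zero-lag dependence across each coupled pair.
    """
    n_ch = strengths.shape[0]
    sources = _ar2_sources(n_ch, n_samples, band, fs, rng)
    deg = (strengths > 0).sum(axis=1).astype(float)
    deg[deg == 0] = 1.0
    mixing = np.eye(n_ch) + strengths / np.sqrt(deg)[:, None]
    return mixing @ sources


def _as_adjacency(topology) -> AdjacencyGraph:
    if isinstance(topology, AdjacencyGraph):
        return topology
    return AdjacencyGraph(np.asarray(topology))


def _as_band(band) -> Band:
    if isinstance(band, Band):
        return band
    low, high = band
    return Band(f"{low:g}-{high:g}Hz", float(low), float(high))


def simulate_coupled_recording(
    topology,
    band,
    strength: float,
    length: int,
    fs: float,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> MultichannelRecording:
    """One band-limited recording with uniform coupling along a graph.

    Each channel is a narrowband AR(2) oscillation plus a shared
    neighbor-source mixture scaled by ``strength`` along the edges of
    ``topology``, plus white noise of standard deviation ``noise_sd``.
    Deterministic given ``seed``.
    """
    g = _as_adjacency(topology)
    b = _as_band(band)
    b.validate_against(fs)
    if strength < 0:
        raise ValueError("coupling strength must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    signal = _coupled_band_signal(strength * g.adj.astype(float), b, int(length), fs, rng)
    signal += noise_sd * rng.standard_normal(signal.shape)
    labels = tuple(f"ch{i + 1:02d}" for i in range(g.n))
    return MultichannelRecording(data=signal, fs=fs, labels=labels, reference="simulated")


def _build_topology(config: SimulationConfig, seed: int) -> tuple[AdjacencyGraph, np.ndarray]:
    """Planted graph plus a boolean mask of its long-range shortcut edges."""
    n = config.n_channels
    npairs = n * (n - 1) // 2
    m = max(1, int(round(config.topology.cost * npairs)))
    if config.topology.model == "ws":
        g = watts_strogatz_matched(n, m, config.topology.rewire_p, seed)
        lattice = regular_lattice_matched(n, m)
        shortcut = (g.adj.astype(bool)) & (~lattice.adj.astype(bool))
    elif config.topology.model == "random":
        g = random_graph_matched(n, m, seed)
        shortcut = np.zeros_like(g.adj, dtype=bool)
    else:
        g = regular_lattice_matched(n, m)
        shortcut = np.zeros_like(g.adj, dtype=bool)
    return g, shortcut


def _effect_band_strengths(
    config: SimulationConfig,
    topology: AdjacencyGraph,
    shortcut_mask: np.ndarray,
    group: str,
    condition: str,
    duration: float | None,
    subject_id: str,
) -> tuple[np.ndarray, float]:
    """Per-edge coupling matrix for the effect band and the cell strength used."""
    base = config.coupling_strength[f"{group}:{condition}"]
    if group == "patient" and duration is not None:
        base = base + config.duration_slope * duration
    if base < 0:
        logger.info(
            "subject %s %s/%s: effect-band strength %.3f clipped to 0",
            subject_id, group, condition, base,
        )
        base = 0.0
    adj = topology.adj.astype(bool)
    weights = np.zeros(adj.shape, dtype=float)
    weights[adj & ~shortcut_mask] = config.lattice_strength
    weights[adj & shortcut_mask] = base
    return weights, base


def simulate_cohort(config: SimulationConfig | None = None) -> CohortDataset:
    """Generate a full two-group, two-condition cohort.

    Every subject gets one recording per condition of
    ``n_epochs * epoch_len`` seconds.  Patient durations are drawn uniform
    over ``duration_range``; the effect-band shortcut coupling of each
    recording is ``base(group, condition) + duration_slope * duration``
    (patients), floored at zero.
    """
    config = config or SimulationConfig()

    topo_seed = int(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(7001,)).generate_state(1)[0]
        % (2**31)
    )
    topology, shortcut_mask = _build_topology(config, topo_seed)

    demo_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(7002,))
    )
    manifest: list[SubjectRecord] = []
    for group in ("patient", "control"):
        for s_idx in range(config.n_per_group):
            age = float(demo_rng.uniform(*config.age_range))
            duration = (
                float(demo_rng.uniform(*config.duration_range)) if group == "patient" else None
            )
            manifest.append(
                SubjectRecord(
                    id=f"{'p' if group == 'patient' else 'c'}{s_idx + 1:02d}",
                    group=group,
                    age=age,
                    duration_years=duration,
                )
            )

    n_samples = config.samples_per_recording
    band_by_name = {b.name: b for b in config.bands}
    recordings: dict[tuple[str, str], MultichannelRecording] = {}
    strengths_used: dict[str, float] = {}
    for subj_idx, rec in enumerate(manifest):
        for cond_idx, condition in enumerate(CONDITIONS):
            ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(subj_idx, cond_idx)
            )
            rng = np.random.default_rng(ss)
            signal = np.zeros((config.n_channels, n_samples))
            for band in config.bands:
                if band.name == config.effect_band:
                    weights, used = _effect_band_strengths(
                        config, topology, shortcut_mask, rec.group, condition,
                        rec.duration_years, rec.id,
                    )
                    strengths_used[f"{rec.id}:{condition}"] = used
                else:
                    bg = config.background_strengths.get(band.name, 0.0)
                    weights = bg * topology.adj.astype(float)
                signal += _coupled_band_signal(weights, band, n_samples, config.fs, rng)
            signal += config.noise_sd * rng.standard_normal(signal.shape)
            labels = tuple(f"ch{i + 1:02d}" for i in range(config.n_channels))
            recordings[(rec.id, condition)] = MultichannelRecording(
                data=signal, fs=config.fs, labels=labels, reference="simulated"
            )

    iu, ju = np.nonzero(np.triu(topology.adj, k=1))
    sc = np.triu(shortcut_mask, k=1)
    ground_truth = {
        "seed": config.seed,
        "topology_model": config.topology.model,
        "edges": [[int(i), int(j)] for i, j in zip(iu, ju)],
        "shortcut_edges": [[int(i), int(j)] for i, j in zip(*np.nonzero(sc))],
        "effect_band": config.effect_band,
        "lattice_strength": config.lattice_strength,
        "effect_band_strengths": strengths_used,
        "background_strengths": dict(config.background_strengths),
    }
    return CohortDataset(recordings=recordings, manifest=manifest, ground_truth=ground_truth)
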