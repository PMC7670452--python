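"""Synthetic HD-sEMG generator with known ground truth.

Emulates the map-level statistics of monopolar grid recordings during
isometric elbow tasks: motor-unit action potentials (MUAPs) propagating along
the column (fiber) axis, smooth per-muscle spatial intensity fields whose
amplitude scales with effort, additive white noise and 50 Hz line
interference, a two-channel torque trace with the task-dependent sign
convention, and injectable bad-channel artifacts. Every quantity a downstream
stage estimates (task, effort, activation centroids, bad channels) is stored
as ground truth.

The generator is intentionally not a volume-conductor model: it reproduces
the statistics that the activation-map pipeline consumes, not physiological
MUAP shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, fftconvolve, sosfiltfilt

from .grids import ElectrodeGrid, default_grids, grid_to_channels
from .recording import MultiChannelRecording

__all__ = [
    "SimulationConfig", "SyntheticRecording", "ArtifactSpec",
    "simulate_muap_train", "simulate_recording", "inject_artifacts",
    "simulate_torque", "make_dataset",
    "TASKS", "EFFORTS", "MUSCLES", "TASK_ACTIVATION", "default_intensity_centers",
]

TASKS = ("flexion", "extension", "supination", "pronation")
EFFORTS = (10, 30, 50)
#: The five recorded muscles; the first three lie under the forearm array.
MUSCLES = ("brachioradialis", "anconeus", "pronator_teres", "biceps", "triceps")
MUSCLE_GRID = {"brachioradialis": 0, "anconeus": 0, "pronator_teres": 0,
               "biceps": 1, "triceps": 2}

#: Relative activation weight of each muscle per task. Agonist/antagonist
#: structure mirrors the muscle subsets used by the 2-step classifier:
#: biceps+triceps for flexion/extension, biceps+brachioradialis+anconeus for
#: supination, pronator teres+anconeus for pronation.
TASK_ACTIVATION = {
    "flexion":    {"biceps": 1.0, "brachioradialis": 0.7, "triceps": 0.10,
                   "anconeus": 0.10, "pronator_teres": 0.10},
    "extension":  {"triceps": 1.0, "anconeus": 0.60, "biceps": 0.10,
                   "brachioradialis": 0.10, "pronator_teres": 0.10},
    "supination": {"biceps": 0.8, "brachioradialis": 0.65, "anconeus": 0.50,
                   "triceps": 0.10, "pronator_teres": 0.15},
    "pronation":  {"pronator_teres": 1.0, "anconeus": 0.60, "biceps": 0.15,
                   "triceps": 0.10, "brachioradialis": 0.10},
}

# MUAP surrogate: first derivative of a Gaussian (biphasic), total width ~6 ms.
_TEMPLATE_SIGMA_S = 1e-3
_MUAP_AMP = 2.0  # peak template amplitude at weight 1, 100 %MVC


def default_intensity_centers(grids: list[ElectrodeGrid]) -> dict:
    """Anatomically-motivated (grid, row, col) activation centroid per muscle.

    Forearm muscles occupy adjacent column bands of array 1 (brachioradialis
    medial, anconeus central, pronator teres lateral); biceps and triceps sit
    centrally under arrays 2 and 3.
    """
    fc = grids[0].n_cols
    return {
        "brachioradialis": (0, 2.5, 0.16 * (fc - 1)),
        "anconeus": (0, 2.5, 0.50 * (fc - 1)),
        "pronator_teres": (0, 2.5, 0.84 * (fc - 1)),
        "biceps": (1, 3.5, 7.0),
        "triceps": (2, 3.5, 7.0),
    }


@dataclass(frozen=True)
class ArtifactSpec:
    """One bad-channel injection: ``kind`` applied to ``channel`` of grid ``grid``."""
    channel: int
    kind: str
    magnitude: float | None = None
    grid: int = 0

    KINDS = ("lowfreq_transient", "line_contam", "dead", "high_power", "decorrelated")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}; "
                             f"expected one of {self.KINDS}")


@dataclass(frozen=True)
class SimulationConfig:
    grids: tuple[ElectrodeGrid, ...] = None
    fs: float = 2048.0
    duration: float = 10.0
    task: str = "flexion"
    effort: float = 30.0
    sources_per_muscle: int = 3
    conduction_velocity: float = 4.0  # m/s
    firing_rate: float = 13.0  # Hz, mean per source
    intensity_centers: dict | None = None  # muscle -> (grid, row, col)
    sigma_col: float = 2.0  # spatial decay across columns, electrode units
    sigma_row: float = 3.0  # spatial decay across rows, electrode units
    centroid_jitter: float = 0.5  # per-source sd around the muscle centroid
    noise_rms: float = 0.05  # additive white noise, a.u.
    line_amp: float = 0.01  # 50 Hz interference amplitude, a.u.
    gain_jitter: float = 0.1  # sd of per-channel log-gain
    amplitude_drift: float = 0.2  # sd of slow per-muscle log-amplitude drift
    mvc_reference: float = 50.0  # Nm
    torque_jitter: float = 0.02
    artifact_specs: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.grids is None:
            object.__setattr__(self, "grids", tuple(default_grids()))
        else:
            object.__setattr__(self, "grids", tuple(self.grids))
        if not self.grids:
            raise ValueError("grid list must not be empty")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 0 < self.effort <= 100:
            raise ValueError("effort must be in (0, 100] %MVC")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.intensity_centers is None:
            object.__setattr__(self, "intensity_centers",
                               default_intensity_centers(list(self.grids)))
        for spec in self.artifact_specs:
            if not 0 <= spec.grid < len(self.grids):
                raise ValueError(f"artifact grid {spec.grid} does not exist")
            if not 0 <= spec.channel < self.grids[spec.grid].n_channels:
                raise ValueError(
                    f"artifact channel {spec.channel} outside grid {spec.grid}")


@dataclass
class SyntheticRecording:
    """Per-array recordings plus torque and the generating ground truth.

    ``truth`` keys: task, effort, centers (muscle -> (grid,row,col)),
    bad_channels (grid index -> {channel: artifact kind}).
    """
    recordings: list[MultiChannelRecording]
    torque: np.ndarray  # (2, n_samples)
    truth: dict
    config: SimulationConfig | None = None

    def __post_init__(self):
        n = self.recordings[0].n_samples
        if self.torque.shape != (2, n):
            raise ValueError("torque must be a 2-channel trace matching the signals")
        for g, bad in self.truth.get("bad_channels", {}).items():
            nch = self.recordings[g].n_channels
            if any(not 0 <= ch < nch for ch in bad):
                raise ValueError("bad-channel id outside its grid")


def _muap_template(fs: float) -> np.ndarray:
    sig = _TEMPLATE_SIGMA_S
    t = np.arange(-3 * sig, 3 * sig + 0.5 / fs, 1.0 / fs)
    w = -t / sig * np.exp(-t**2 / (2 * sig**2))
    return w / np.abs(w).max()


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    out = np.zeros_like(x)
    if lag >= 0:
        out[lag:] = x[:len(x) - lag] if lag < len(x) else 0.0
    else:
        out[:lag] = x[-lag:]
    return out


def simulate_muap_train(grid: ElectrodeGrid, source_pos: tuple[float, float],
                        velocity: float, firing_rate: float, fs: float,
                        duration: float, seed: int, *, amplitude: float = 1.0,
                        sigma_col: float = 2.0, sigma_row: float = 3.0,
                        isi_cv: float = 0.12) -> np.ndarray:
    """MUAP train of one source, observed by every channel of ``grid``.

    Each firing places a biphasic template on the source column; rows at
    distance d see it delayed by d*ied/velocity (propagation along the fiber
    axis) and attenuated by a Gaussian spatial profile in both directions.
    Returns a channels x samples matrix in the grid's channel order.
    """
    row0, col0 = source_pos
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if not (0 <= row0 <= grid.n_rows - 1 and 0 <= col0 <= grid.n_cols - 1):
        raise ValueError(f"source {source_pos} outside {grid.shape} grid")
    n = int(round(duration * fs))
    out = np.zeros((grid.n_rows, grid.n_cols, n))
    if firing_rate > 0:
        rng = np.random.default_rng(seed)
        impulses = np.zeros(n)
        t = rng.uniform(0, 1.0 / firing_rate)
        mean_isi = 1.0 / firing_rate
        while t < duration:
            impulses[int(t * fs)] += 1.0
            isi = mean_isi * (1.0 + isi_cv * rng.standard_normal())
            t += max(isi, 0.25 * mean_isi)
        base = fftconvolve(impulses, _muap_template(fs), mode="same")
        ied_m = grid.ied_mm / 1000.0
        rows = np.arange(grid.n_rows)
        cols = np.arange(grid.n_cols)
        col_amp = np.exp(-(cols - col0) ** 2 / (2 * sigma_col**2))
        row_amp = np.exp(-(rows - row0) ** 2 / (2 * sigma_row**2))
        for r in rows:
            lag = int(round(abs(r - row0) * ied_m / velocity * fs))
            out[r] = (amplitude * row_amp[r] * col_amp)[:, None] * _shift(base, lag)
    return grid_to_channels(out, grid)


def simulate_torque(task: str, effort: float, fs: float, duration: float,
                    mvc_reference: float, *, jitter: float = 0.02,
                    ramp_s: float = 0.5, seed: int = 0) -> np.ndarray:
    """Two-channel torque trace with ramps, a plateau and low-frequency jitter.

    The two torque meters give equal signs for flexion (+) and extension (-),
    and opposite signs for supination (ch1 +) and pronation (ch1 -), matching
    the mechanical-brace convention.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    plateau = effort / 100.0 * mvc_reference
    env = np.ones(n)
    nr = int(round(ramp_s * fs))
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = ramp
        env[-nr:] = ramp[::-1]
    base = plateau * env
    signs = {"flexion": (1, 1), "extension": (-1, -1),
             "supination": (1, -1), "pronation": (-1, 1)}[task]
    out = np.empty((2, n))
    rng = np.random.default_rng(seed)
    for k in range(2):
        if jitter > 0:
            sos = butter(2, 2.0, btype="low", fs=fs, output="sos")
            w = sosfiltfilt(sos, rng.standard_normal(n))
            w = w / (np.std(w) + 1e-30) * jitter * plateau
        else:
            w = 0.0
        out[k] = signs[k] * (base + w * env)
    return out


def simulate_recording(config: SimulationConfig) -> SyntheticRecording:
    """Full synthetic trial: per-array signals, torque, and ground truth.

    The per-muscle spatial RMS field peaks at the configured centroid (up to
    per-source placement jitter) and its amplitude scales linearly with
    effort, so grid-mean RMS is monotone in effort at a fixed seed.
    """
    ss = np.random.SeedSequence(config.seed)
    grid_seeds = ss.spawn(len(config.grids))
    torque_seed = ss.spawn(1)[0]
    n = int(round(config.duration * config.fs))

    recordings = []
    realized: dict[str, tuple[int, float, float]] = {}
    for g, grid in enumerate(config.grids):
        g_ss = grid_seeds[g]
        rng = np.random.default_rng(g_ss)
        sig = np.zeros((grid.n_channels, n))
        for muscle, (mg, row0, col0) in sorted(config.intensity_centers.items()):
            if mg != g:
                continue
            weight = TASK_ACTIVATION[config.task].get(muscle, 0.05)
            amp = _MUAP_AMP * weight * config.effort / 100.0
            msig = np.zeros_like(sig)
            positions, amps = [], []
            for s in range(config.sources_per_muscle):
                r = np.clip(row0 + config.centroid_jitter * rng.standard_normal(),
                            0, grid.n_rows - 1)
                c = np.clip(col0 + config.centroid_jitter * rng.standard_normal(),
                            0, grid.n_cols - 1)
                src_seed = int(rng.integers(2**31))
                a = amp * (1.0 + 0.2 * rng.uniform(-1, 1))
                msig += simulate_muap_train(
                    grid, (r, c), config.conduction_velocity,
                    config.firing_rate, config.fs, config.duration, src_seed,
                    amplitude=a,
                    sigma_col=config.sigma_col, sigma_row=config.sigma_row)
                positions.append((r, c))
                amps.append(a)
            if config.amplitude_drift > 0 and positions:
                # common-drive fluctuation: the muscle's net output drifts
                # slowly (~0.3 Hz) around the target effort, a well-known
                # feature of sustained voluntary contractions
                sos = butter(2, 0.3, btype="low", fs=config.fs, output="sos")
                env = sosfiltfilt(sos, rng.standard_normal(n))
                env = env / (np.std(env) + 1e-30) * config.amplitude_drift
                msig *= np.exp(env - env.mean())[None, :]
            sig += msig
            if positions:
                # amplitude-weighted mean source position: the centroid the
                # recording actually carries, given per-source placement jitter
                wts = np.asarray(amps) / np.sum(amps)
                pr = float(np.dot(wts, [p[0] for p in positions]))
                pc = float(np.dot(wts, [p[1] for p in positions]))
                realized[muscle] = (g, pr, pc)
        if config.noise_rms > 0:
            sig += config.noise_rms * rng.standard_normal(sig.shape)
        if config.line_amp > 0:
            t = np.arange(n) / config.fs
            phase = rng.uniform(0, 2 * np.pi)
            ch_amp = config.line_amp * (1.0 + 0.3 * rng.uniform(-1, 1, sig.shape[0]))
            sig += ch_amp[:, None] * np.sin(2 * np.pi * 50.0 * t + phase)
        if config.gain_jitter > 0:
            sig *= np.exp(config.gain_jitter *
                          rng.standard_normal(sig.shape[0]))[:, None]
        recordings.append(MultiChannelRecording(
            signals=sig, fs=config.fs, grid=grid,
            task=config.task, effort=config.effort))

    torque = simulate_torque(config.task, config.effort, config.fs,
                             config.duration, config.mvc_reference,
                             jitter=config.torque_jitter,
                             seed=int(np.random.default_rng(torque_seed)
                                      .integers(2**31)))
    truth = {"task": config.task, "effort": config.effort,
             "centers": dict(config.intensity_centers),
             "realized_centers": realized,
             "bad_channels": {}}
    rec = SyntheticRecording(recordings=recordings, torque=torque,
                             truth=truth, config=config)
    if config.artifact_specs:
        rec = inject_artifacts(rec, list(config.artifact_specs),
                               seed=int(np.random.default_rng(
                                   ss.spawn(1)[0]).integers(2**31)))
    return rec


_DEFAULT_MAG = {"lowfreq_transient": 5.0, "line_contam": 5.0,
                "high_power": 5.0, "dead": 1e-3, "decorrelated": 1.0}


def inject_artifacts(rec: SyntheticRecording, specs: list[ArtifactSpec],
                     *, seed: int = 0) -> SyntheticRecording:
    """Return a copy of ``rec`` with the named channels corrupted.

    Artifact kinds: ``lowfreq_transient`` (large slow drift, as caused by
    cable/skin movement), ``line_contam`` (strong residual 50 Hz and
    harmonics from poor electrode-skin contact), ``dead`` (near-zero signal),
    ``high_power`` (amplified channel), ``decorrelated`` (white noise at the
    channel's own power, uncorrelated with its neighbors). All other channels
    are bit-identical to the input; ``truth['bad_channels']`` is updated.
    """
    rng = np.random.default_rng(seed)
    new_recs = []
    bad = {g: dict(v) for g, v in rec.truth.get("bad_channels", {}).items()}
    for g, r in enumerate(rec.recordings):
        sig = r.signals.copy()
        fs, n = r.fs, r.n_samples
        grid_specs = [s for s in specs if s.grid == g]
        if grid_specs:
            med_rms = np.median(np.sqrt(np.mean(sig**2, axis=1)))
            t = np.arange(n) / fs
            for s in grid_specs:
                if not 0 <= s.channel < sig.shape[0]:
                    raise ValueError(f"artifact channel {s.channel} outside grid {g}")
                mag = s.magnitude if s.magnitude is not None else _DEFAULT_MAG[s.kind]
                ch = s.channel
                if s.kind == "dead":
                    sig[ch] = mag * med_rms * rng.standard_normal(n)
                elif s.kind == "high_power":
                    sig[ch] = sig[ch] * mag
                elif s.kind == "line_contam":
                    add = np.zeros(n)
                    for h, rel in ((50, 1.0), (100, 0.25), (150, 0.25)):
                        add += rel * np.sin(2 * np.pi * h * t +
                                            rng.uniform(0, 2 * np.pi))
                    sig[ch] = sig[ch] + mag * med_rms * np.sqrt(2) * add
                elif s.kind == "lowfreq_transient":
                    drift = np.zeros(n)
                    for _ in range(4):
                        f = rng.uniform(0.3, 5.0)
                        drift += rng.uniform(0.5, 1) * np.sin(
                            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                    drift *= mag * med_rms / (np.sqrt(np.mean(drift**2)) + 1e-30)
                    sig[ch] = sig[ch] + drift
                elif s.kind == "decorrelated":
                    rms_ch = max(np.sqrt(np.mean(sig[ch]**2)), 1e-30)
                    sig[ch] = mag * rms_ch * rng.standard_normal(n)
                bad.setdefault(g, {})[ch] = s.kind
        new_recs.append(MultiChannelRecording(
            signals=sig, fs=r.fs, grid=r.grid, subject=r.subject,
            task=r.task, effort=r.effort, gain=r.gain, meta=dict(r.meta)))
    truth = dict(rec.truth)
    truth["bad_channels"] = bad
    return SyntheticRecording(recordings=new_recs, torque=rec.torque.copy(),
                              truth=truth, config=rec.config)


def make_dataset(seed: int, *, tasks=TASKS, efforts=EFFORTS, n_reps: int = 1,
                 base_config: SimulationConfig | None = None) -> list[SyntheticRecording]:
    """One synthetic 'subject': a recording per (task, effort, repetition).

    Recordings share the subject's anatomy (muscle centroids) but differ in
    firing realizations, noise, per-channel gains and torque jitter, the
    nuisance variation a classifier must be robust to.
    """
    if base_config is None:
        base_config = SimulationConfig()
    ss = np.random.SeedSequence(seed)
    out = []
    combos = [(t, e, r) for t in tasks for e in efforts for r in range(n_reps)]
    for (task, effort, _), child in zip(combos, ss.spawn(len(combos))):
        cfg = replace(base_config, task=task, effort=float(effort),
                      seed=int(np.random.default_rng(child).integers(2**31)))
        out.append(simulate_recording(cfg))
    return out
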