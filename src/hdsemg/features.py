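"""Feature sets for myoelectric task/effort identification.

Four sets are built from 150 ms epochs of the stability window:

* ``I``   — per-muscle intensity: log10 of the mean activation-map value over
            the muscle's segmented region (five muscles -> five scalars);
* ``IMS`` — the five intensities concatenated with mean-shift mode
            descriptors of each array's map (spatial information), the
            mean-shift block reduced by PCA at classification time;
* ``ICG`` — the five intensities concatenated with the per-muscle centers of
            gravity of the map;
* ``TD``  — the classical time-domain set (RMS, mean absolute value, zero
            crossings, waveform length, slope-sign changes) for every
            channel, reduced by PCA at classification time.

PCA models keep the minimal prefix of components whose cumulative explained
variance exceeds 90%, and are always fit on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .maps import ActivationMap, average_maps, compute_am, segment_for_muscles
from .preprocessing import EpochSpec, bandpass_zero_phase, epoch_signal, \
    select_stability_window
from .simulate import MUSCLE_GRID, MUSCLES, SyntheticRecording

__all__ = ["FeatureSet", "PcaModel", "intensity_feature", "meanshift_features",
           "cog_feature", "td_features", "pca_reduce", "pca_apply",
           "build_feature_set", "select_muscles", "FEATURE_KINDS"]

FEATURE_KINDS = ("I", "IMS", "ICG", "TD")
TD_NAMES = ("rms", "mav", "zc", "wl", "ssc")


def intensity_feature(map_values: np.ndarray, region_mask: np.ndarray) -> float:
    """Intensity of a segmented region: I = log10(mean AM over its M pixels)."""
    v = np.asarray(map_values, dtype=float)
    m = np.asarray(region_mask, dtype=bool)
    if not m.any():
        raise ValueError("region mask is empty")
    mean = float(v[m].mean())
    if mean <= 0:
        raise ValueError("region mean must be positive for the log10 intensity")
    return float(np.log10(mean))


def cog_feature(map_values: np.ndarray,
                region_mask: np.ndarray | None = None) -> tuple[float, float]:
    """Amplitude-weighted center of gravity of a map, as (x, y) = (col, row)."""
    v = np.asarray(map_values, dtype=float)
    if region_mask is not None:
        v = np.where(np.asarray(region_mask, bool), v, 0.0)
    total = v.sum()
    if total <= 0:
        raise ValueError("center of gravity undefined for an all-zero map")
    rows, cols = np.indices(v.shape)
    return (float((cols * v).sum() / total), float((rows * v).sum() / total))


_UNIFORM_PEAK_CACHE: dict = {}


def _uniform_kde_peak(shape: tuple[int, int], bandwidth: float) -> float:
    """Peak of the KDE of a uniform-amplitude map of this geometry (the
    no-localized-activation reference for mode significance)."""
    key = (shape, bandwidth)
    if key not in _UNIFORM_PEAK_CACHE:
        rows, cols = np.indices(shape)
        pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        dens = np.exp(-d2 / (2 * bandwidth**2)).mean(1)
        _UNIFORM_PEAK_CACHE[key] = float(dens.max()) / (2 * np.pi
                                                        * bandwidth**2)
    return _UNIFORM_PEAK_CACHE[key]


def meanshift_features(map_values: np.ndarray, bandwidth: float = 2.0,
                       n_modes: int = 3, *, n_starts: int = 20,
                       seed: int = 0, tol: float = 1e-4,
                       max_iter: int = 200,
                       significance_ratio: float = 1.1) -> np.ndarray:
    """Mean-shift mode descriptors of the pixel-amplitude density of a map.

    Pixel coordinates weighted by amplitude define a kernel density estimate
    (Gaussian kernel, ``bandwidth`` in electrode units, weights normalized to
    sum 1). Mean-shift ascends its gradient from every local grid maximum
    plus ``n_starts`` seeded random starts (set ``n_starts=0`` for a fully
    deterministic descriptor; the local-maxima starts cover the KDE modes of
    these small maps); converged positions closer than bandwidth/2 are
    merged. Output: the top ``n_modes`` modes by density as (x, y, density)
    triplets, ordered spatially (by x, then y) so that the descriptor is
    stable across consecutive epochs even when mode densities are close;
    missing modes repeat the dominant mode. Flat array of length 3*n_modes.

    A map without localized activation — KDE peak below
    ``significance_ratio`` times the peak of a uniform-amplitude map of the
    same geometry — returns the all-zero descriptor: its mode position is
    noise-driven wandering, and 'no significant mode' is itself
    informative. Set ``significance_ratio=0`` to disable the gate (the
    dataset-level feature builder does, deciding significance once per
    recording on the averaged map so consecutive epochs cannot flap).
    """
    v = np.asarray(map_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty map")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    w = np.clip(v, 0, None).ravel()
    total = w.sum()
    rows, cols = np.indices(v.shape)
    pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)  # (x, y)
    out = np.zeros(3 * n_modes)
    if total <= 0:
        return out
    w = w / total

    rng = np.random.default_rng(seed)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    starts = [rng.uniform(lo, hi, size=2) for _ in range(n_starts)]
    # deterministic extra starts: strict local maxima on the 3x3 neighborhood
    from scipy.ndimage import maximum_filter
    local_max = (v == maximum_filter(v, size=3)) & (v > 0)
    for r, c in zip(*np.nonzero(local_max)):
        starts.append(np.array([float(c), float(r)]))
    Y = np.array(starts)  # (n_starts, 2)

    inv2b2 = 1.0 / (2.0 * bandwidth**2)
    for _ in range(max_iter):
        d2 = ((Y[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        K = w[None, :] * np.exp(-d2 * inv2b2)
        denom = K.sum(axis=1, keepdims=True)
        newY = np.where(denom > 1e-300, K @ pts / np.maximum(denom, 1e-300), Y)
        step = np.sqrt(((newY - Y) ** 2).sum(-1)).max()
        Y = newY
        if step < tol:
            break

    # KDE density at the converged positions
    d2 = ((Y[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    dens = (w[None, :] * np.exp(-d2 * inv2b2)).sum(axis=1) / (2 * np.pi * bandwidth**2)

    # merge modes closer than bandwidth/2, keeping the densest representative
    order = np.argsort(dens)[::-1]
    modes: list[tuple[np.ndarray, float]] = []
    for i in order:
        if all(np.linalg.norm(Y[i] - m[0]) >= bandwidth / 2 for m in modes):
            modes.append((Y[i], float(dens[i])))
    top = modes[:n_modes]
    if not top:
        return out
    if significance_ratio > 0 and top[0][1] < significance_ratio * \
            _uniform_kde_peak(v.shape, bandwidth):
        return out
    while len(top) < n_modes:
        top.append(top[0])  # repeat the dominant mode instead of zero-padding
    top.sort(key=lambda m: (m[0][0], m[0][1]))
    for j, (pos, den) in enumerate(top):
        out[3 * j:3 * j + 3] = (pos[0], pos[1], den)
    return out


def td_features(epoch: np.ndarray, deadband: float = 0.0) -> np.ndarray:
    """The five classical time-domain features per channel.

    RMS, mean absolute value (MAV), zero crossings (ZC, sign changes whose
    amplitude step exceeds the deadband), waveform length (WL, total
    variation), and slope-sign changes (SSC, local extrema whose neighboring
    steps exceed the deadband). Input (n,) or (channels, n); output
    (channels, 5) ordered (rms, mav, zc, wl, ssc).
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    if x.shape[-1] < 3:
        raise ValueError("epoch must have at least 3 samples")
    d = np.diff(x, axis=-1)
    rms_v = np.sqrt(np.mean(x**2, axis=-1))
    mav = np.mean(np.abs(x), axis=-1)
    zc = np.sum((x[:, :-1] * x[:, 1:] < 0) & (np.abs(d) >= deadband), axis=-1)
    wl = np.sum(np.abs(d), axis=-1)
    ssc = np.sum((d[:, :-1] * d[:, 1:] < 0)
                 & (np.maximum(np.abs(d[:, :-1]), np.abs(d[:, 1:])) >= deadband),
                 axis=-1)
    out = np.column_stack([rms_v, mav, zc.astype(float), wl, ssc.astype(float)])
    return out if np.asarray(epoch).ndim > 1 else out[0].reshape(1, 5)


def dominant_mode(descriptor: np.ndarray) -> tuple[float, float]:
    """(x, y) of the highest-density triplet in a mean-shift descriptor."""
    d = np.asarray(descriptor, dtype=float).reshape(-1, 3)
    j = int(np.argmax(d[:, 2]))
    return (float(d[j, 0]), float(d[j, 1]))


@dataclass
class PcaModel:
    """PCA with the >90% cumulative-explained-variance retention rule."""
    mean: np.ndarray
    components: np.ndarray  # (n_retained, n_features)
    explained_variance_ratio: np.ndarray  # all fitted components
    n_retained: int
    threshold: float


def pca_reduce(train_vectors: np.ndarray, threshold: float = 0.90) -> PcaModel:
    """Fit PCA on training vectors; retain the minimal prefix of components
    whose cumulative explained variance strictly exceeds ``threshold``."""
    X = np.asarray(train_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    n_keep = int(np.searchsorted(cum, threshold, side="right")) + 1
    n_keep = min(n_keep, len(evr))
    return PcaModel(mean=pca.mean_, components=pca.components_[:n_keep],
                    explained_variance_ratio=evr, n_retained=n_keep,
                    threshold=threshold)


def pca_apply(model: PcaModel, vectors: np.ndarray) -> np.ndarray:
    """Project vectors onto the retained components (centered with the
    training mean)."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    return (X - model.mean) @ model.components.T


@dataclass
class FeatureSet:
    """Epoch-wise feature matrix with label and column provenance.

    ``muscle_cols`` maps each muscle to the columns carrying its features
    (the 2-step classifier restricts to task-specific muscle subsets);
    ``pca_cols`` lists the columns to be PCA-reduced per training split.
    """
    kind: str
    X: np.ndarray  # (n_epochs, n_features)
    tasks: np.ndarray  # task label per epoch
    efforts: np.ndarray  # %MVC label per epoch
    muscle_cols: dict = field(default_factory=dict)
    pca_cols: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    recording_ids: np.ndarray | None = None

    def __post_init__(self):
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def select_muscles(fs: FeatureSet, muscles: list[str]) -> FeatureSet:
    """Restrict a feature set to the columns of the given muscles."""
    cols: list[int] = []
    for m in muscles:
        if m not in fs.muscle_cols:
            raise ValueError(f"feature set has no columns for muscle {m!r}")
        for c in fs.muscle_cols[m]:
            if c not in cols:
                cols.append(c)
    cols_arr = np.array(sorted(cols), dtype=int)
    remap = {c: i for i, c in enumerate(cols_arr)}
    new_muscle_cols = {m: [remap[c] for c in fs.muscle_cols[m]]
                       for m in muscles}
    new_pca = np.array([remap[c] for c in fs.pca_cols if c in remap], dtype=int)
    return FeatureSet(kind=fs.kind, X=fs.X[:, cols_arr], tasks=fs.tasks,
                      efforts=fs.efforts, muscle_cols=new_muscle_cols,
                      pca_cols=new_pca, recording_ids=fs.recording_ids)


def _recording_maps(rec: SyntheticRecording, *, map_epoch_s: float = 0.5,
                    window_s: float = 3.0,
                    band: tuple[float, float] = (12.0, 350.0)):
    """Filter, locate the stability window, and build the 3 s averaged map
    plus forearm segmentation shared by all of the recording's epochs."""
    fs = rec.recordings[0].fs
    start, end = select_stability_window(rec.torque, fs, window_s=window_s)
    filtered = [bandpass_zero_phase(r.signals, fs, band[0], band[1])
                for r in rec.recordings]
    grids = [r.grid for r in rec.recordings]
    avg_maps = []
    spec = EpochSpec(length_s=map_epoch_s, fs=fs)
    from .grids import channels_to_grid
    for sig, grid in zip(filtered, grids):
        epochs = epoch_signal(sig[:, start:end], spec)
        ms = [compute_am(channels_to_grid(ep, grid), grid=grid) for ep in epochs]
        avg_maps.append(average_maps(ms))
    return filtered, grids, (start, end), avg_maps


def _muscle_refs(rec: SyntheticRecording) -> dict:
    """Per-grid muscle -> reference column, from the recording's truth/anatomy."""
    centers = rec.truth["centers"]
    refs: dict[int, dict[str, float]] = {}
    for muscle, (g, _r, c) in centers.items():
        refs.setdefault(g, {})[muscle] = float(c)
    return refs


def build_feature_set(kind: str, recordings: list[SyntheticRecording], *,
                      epoch_s: float = 0.15, bandwidth: float = 2.0,
                      n_modes: int = 3, seed: int = 0, alpha: float = 0.2,
                      strict_segmentation: bool = False) -> FeatureSet:
    """Extract one of the four feature sets from a list of recordings.

    Per recording: band-pass filter, select the 3 s stability window, build
    the averaged activation map and its per-muscle segmentation (reused by
    all 150 ms epochs of that recording for stability), then compute the
    epoch-wise features of the requested kind.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}")
    from .grids import channels_to_grid
    rows, tasks, efforts, rec_ids = [], [], [], []
    muscle_cols: dict[str, list[int]] = {m: [] for m in MUSCLES}
    pca_cols: np.ndarray = np.array([], dtype=int)
    rng = np.random.default_rng(seed)

    for ri, rec in enumerate(recordings):
        fs = rec.recordings[0].fs
        filtered, grids, (start, end), avg_maps = _recording_maps(rec)
        refs = _muscle_refs(rec)
        segs = {}
        for g, am in enumerate(avg_maps):
            if g in refs:
                segs[g] = segment_for_muscles(am, refs[g], alpha=alpha,
                                              strict=strict_segmentation)
        # mode-significance gate decided once per recording on the stable
        # averaged map, so consecutive epochs cannot flap around threshold
        ms_gate = {g: bool(meanshift_features(am.values, bandwidth=bandwidth,
                                              n_modes=n_modes,
                                              n_starts=0).any())
                   for g, am in enumerate(avg_maps)}
        spec = EpochSpec(length_s=epoch_s, fs=fs)
        n_ep = None
        per_grid_epochs = []
        for sig in filtered:
            eps = epoch_signal(sig[:, start:end], spec)
            per_grid_epochs.append(eps)
            n_ep = eps.shape[0] if n_ep is None else min(n_ep, eps.shape[0])

        ms_seed = int(rng.integers(2**31))
        for e in range(n_ep):
            epoch_maps = [compute_am(channels_to_grid(per_grid_epochs[g][e],
                                                      grids[g]), grid=grids[g])
                          for g in range(len(grids))]
            vec, mc, pc = _epoch_features(
                kind, epoch_maps, per_grid_epochs, e, segs, refs, grids,
                bandwidth=bandwidth, n_modes=n_modes, seed=ms_seed + e,
                ms_gate=ms_gate)
            rows.append(vec)
            tasks.append(rec.truth["task"])
            efforts.append(rec.truth["effort"])
            rec_ids.append(ri)
            muscle_cols, pca_cols = mc, pc

    return FeatureSet(kind=kind, X=np.array(rows), tasks=np.array(tasks),
                      efforts=np.array(efforts, dtype=float),
                      muscle_cols=muscle_cols, pca_cols=pca_cols,
                      recording_ids=np.array(rec_ids))


def _epoch_features(kind, epoch_maps, per_grid_epochs, e, segs, refs, grids,
                    *, bandwidth, n_modes, seed, ms_gate=None):
    """One epoch's feature vector plus column-provenance maps."""
    muscle_cols: dict[str, list[int]] = {}
    vec: list[float] = []
    pca_cols: list[int] = []

    if kind in ("I", "IMS", "ICG"):
        for muscle in MUSCLES:
            g = MUSCLE_GRID[muscle]
            mask = segs[g].masks[muscle]
            vals = epoch_maps[g].values
            region_mean = max(float(vals[mask].mean()), 1e-30)
            muscle_cols.setdefault(muscle, []).append(len(vec))
            vec.append(float(np.log10(region_mean)))

    if kind == "IMS":
        for g, am in enumerate(epoch_maps):
            block_start = len(vec)
            if ms_gate is not None and not ms_gate.get(g, True):
                ms = np.zeros(3 * n_modes)
            else:
                # deterministic starts only, no per-epoch gate: stability
                ms = meanshift_features(am.values, bandwidth=bandwidth,
                                        n_modes=n_modes, n_starts=0,
                                        seed=seed + g, significance_ratio=0)
            vec.extend(ms.tolist())
            cols = list(range(block_start, len(vec)))
            pca_cols.extend(cols)
            for muscle, mg in MUSCLE_GRID.items():
                if mg == g:
                    muscle_cols.setdefault(muscle, []).extend(cols)

    if kind == "ICG":
        for muscle in MUSCLES:
            g = MUSCLE_GRID[muscle]
            mask = segs[g].masks[muscle]
            vals = epoch_maps[g].values
            masked = np.where(mask, vals, 0.0)
            if masked.sum() <= 0:
                x, y = cog_feature(np.where(mask, 1.0, 0.0))
            else:
                x, y = cog_feature(vals, mask)
            muscle_cols.setdefault(muscle, []).extend([len(vec), len(vec) + 1])
            vec.extend([x, y])

    if kind == "TD":
        for g, grid in enumerate(grids):
            td = td_features(per_grid_epochs[g][e])  # (channels, 5)
            block_start = len(vec)
            vec.extend(td.ravel().tolist())
            ch_muscles = _grid_channel_muscles(grid, refs.get(g, {}))
            for ch, muscle in enumerate(ch_muscles):
                cols = list(range(block_start + 5 * ch, block_start + 5 * ch + 5))
                muscle_cols.setdefault(muscle, []).extend(cols)
            pca_cols.extend(range(block_start, len(vec)))

    return np.array(vec), muscle_cols, np.array(pca_cols, dtype=int)


def _grid_channel_muscles(grid, muscle_ref_cols: dict) -> list[str]:
    """Attribute each channel of a grid to its nearest muscle (by reference
    column); single-muscle arrays attribute every channel to that muscle."""
    if not muscle_ref_cols:
        raise ValueError("grid has no muscles to attribute channels to")
    muscles = sorted(muscle_ref_cols)
    out = []
    for ch in range(grid.n_rows * grid.n_cols):
        if ch in grid.missing:
            continue
        _r, c = grid.channel_position(ch)
        out.append(min(muscles, key=lambda m: abs(muscle_ref_cols[m] - c)))
    return out
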