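"""Grid channel-quality assessment and bad-channel repair.

Each channel is characterized by four features inspired by expert criteria
for "good" vs "bad" monopolar channels:

* relative power of low-frequency components (0-12 Hz), sensitive to
  movement artifacts that cause large slow transients;
* relative residual power of line interference (50 Hz and its first four
  harmonics), caused by poor electrode-skin contact;
* signal power (RMS over 500 ms epochs), to find channels with much higher
  or lower power than their neighbors;
* similitude to the adjacent (horizontal, vertical and diagonal) channels,
  as the average maximum cross-correlation coefficient.

Because an array can cover simultaneously active and silent regions, the
power and similarity features are referred to a local spatial neighborhood
rather than to the bulk of the grid. A channel exceeding a threshold on ANY
feature is an outlier (rule mode); an unsupervised alternative scores
channels with the local distance-based outlier factor (LDOF) in feature
space. Flagged channels are repaired by iterative neighbor interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .grids import ElectrodeGrid
from .preprocessing import EpochSpec, epoch_signal, rms

__all__ = ["ChannelFeatures", "QualityThresholds", "QualityReport",
           "compute_channel_features", "detect_outliers_rules",
           "ldof_scores", "detect_outliers_ldof", "replace_bad_channels",
           "outlier_percent"]

LINE_HARMONICS = (50.0, 100.0, 150.0, 200.0, 250.0)


@dataclass
class ChannelFeatures:
    """Per-channel quality features (vectorized over the grid's channels)."""
    p_low_rel: np.ndarray      # fraction of power in 0-12 Hz
    p_line_rel: np.ndarray     # fraction of power at 50 Hz + 4 harmonics (+-1 Hz)
    rms_epochs: np.ndarray     # (n_channels, n_epochs) RMS per 500 ms epoch
    neighbor_xcorr: np.ndarray # mean max cross-correlation with adjacent channels
    grid: ElectrodeGrid | None = None

    def __post_init__(self):
        for name in ("p_low_rel", "p_line_rel"):
            v = getattr(self, name)
            if np.any((v < -1e-9) | (v > 1 + 1e-9)):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def rms_channel(self) -> np.ndarray:
        """Median per-epoch RMS, a robust per-channel power summary."""
        return np.median(self.rms_epochs, axis=1)

    def matrix(self) -> np.ndarray:
        """Feature matrix (n_channels x 4) for unsupervised scoring."""
        with np.errstate(divide="ignore"):
            log_rms = np.log10(np.maximum(self.rms_channel, 1e-30))
        return np.column_stack([self.p_low_rel, self.p_line_rel,
                                log_rms, self.neighbor_xcorr])


def compute_channel_features(signals: np.ndarray, grid: ElectrodeGrid,
                             fs: float, epoch_s: float = 0.5,
                             max_lag_ms: float = 10.0,
                             line_tol_hz: float = 2.0) -> ChannelFeatures:
    """Compute the four quality features for every channel of one array.

    Spectral fractions come from an averaged periodogram over ``epoch_s``
    epochs (Welch, Hann window, no overlap; the +-2 Hz line tolerance covers
    the Hann mainlobe at the resulting 2 Hz bin spacing). The similarity feature is the
    normalized cross-correlation maximized over lags within ``max_lag_ms``
    (tolerating propagation delays between rows), averaged over the
    8-connected neighbors; border channels use the neighbors they have.
    Computed on raw monopolar signals so the low-frequency band is intact.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n = signals.shape
    if n_ch != grid.n_channels:
        raise ValueError("signal/grid channel count mismatch")
    if n_ch < 2:
        raise ValueError("neighbor features undefined on a single-channel grid")

    nper = min(int(epoch_s * fs), n)
    freqs, psd = welch(signals, fs=fs, window="hann", nperseg=nper,
                       noverlap=0, detrend=False, axis=-1)
    total = psd.sum(axis=-1) + 1e-300
    p_low = psd[:, freqs <= 12.0].sum(axis=-1) / total
    line_mask = np.zeros_like(freqs, dtype=bool)
    for h in LINE_HARMONICS:
        line_mask |= np.abs(freqs - h) <= line_tol_hz
    p_line = psd[:, line_mask].sum(axis=-1) / total

    spec = EpochSpec(length_s=epoch_s, fs=fs)
    rms_ep = rms(epoch_signal(signals, spec)).T  # (n_channels, n_epochs)

    # neighbor cross-correlation, vectorized over pairs per lag
    pairs = []
    for ch in range(grid.n_rows * grid.n_cols):
        if ch in grid.missing:
            continue
        r, c = grid.channel_position(ch)
        for nb in grid.neighbor_indices(r, c, radius=1):
            if nb not in grid.missing and nb > ch:
                pairs.append((ch, nb))
    pairs = np.asarray(pairs)
    centered = signals - signals.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centered**2, axis=1)) + 1e-300
    max_lag = int(round(max_lag_ms / 1000.0 * fs))
    a, b = centered[pairs[:, 0]], centered[pairs[:, 1]]
    best = np.full(len(pairs), -np.inf)
    for lag in range(0, max_lag + 1):
        sl = n - lag
        fwd = np.einsum("ij,ij->i", a[:, :sl], b[:, lag:])
        best = np.maximum(best, fwd)
        if lag:
            bwd = np.einsum("ij,ij->i", a[:, lag:], b[:, :sl])
            best = np.maximum(best, bwd)
    pair_cc = best / (norms[pairs[:, 0]] * norms[pairs[:, 1]])
    acc = np.zeros(n_ch)
    cnt = np.zeros(n_ch)
    np.add.at(acc, pairs[:, 0], pair_cc)
    np.add.at(acc, pairs[:, 1], pair_cc)
    np.add.at(cnt, pairs[:, 0], 1)
    np.add.at(cnt, pairs[:, 1], 1)
    nb_xcorr = acc / np.maximum(cnt, 1)

    return ChannelFeatures(p_low_rel=np.clip(p_low, 0, 1),
                           p_line_rel=np.clip(p_line, 0, 1),
                           rms_epochs=rms_ep, neighbor_xcorr=nb_xcorr,
                           grid=grid)


@dataclass(frozen=True)
class QualityThresholds:
    """Rule-mode thresholds (the expert system's exact values are not public;
    these robust defaults are configurable).

    Both the power and the similarity rules are *relative to the spatial
    neighborhood*: an array can cover strongly and weakly active muscles at
    once, so a quiet, noise-dominated region must not be flagged wholesale.
    """
    rms_z: float = 5.0          # neighborhood log-RMS residual, in MAD units
    p_low_max: float = 0.5
    p_line_max: float = 0.5
    xcorr_drop: float = 0.35    # patch-median xcorr minus own xcorr
    neighborhood_radius: int = 2
    mad_floor: float = 0.05     # floor on the residual MAD (log10 units)


@dataclass
class QualityReport:
    flags: np.ndarray                  # bool per channel
    rules: list = field(default_factory=list)  # triggering rule names per channel
    method: str = "rules"
    scores: np.ndarray | None = None   # LDOF scores when method == "ldof"

    @property
    def flagged_channels(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    @property
    def fraction_flagged(self) -> float:
        return float(np.mean(self.flags))


def detect_outliers_rules(features: ChannelFeatures, grid: ElectrodeGrid,
                          thresholds: QualityThresholds | None = None
                          ) -> QualityReport:
    """Flag channels whose features exceed any threshold (OR combination).

    Power rule: the residual of each channel's log-RMS from the median of
    its 8-connected neighbors (which tracks the smooth spatial activation
    field) is compared, in robust-z units, against the residual spread over
    the (2r+1)^2 patch. Similarity rule: a channel is flagged when its mean
    neighbor cross-correlation falls ``xcorr_drop`` below the patch median
    (an absolute floor would flag whole noise-dominated quiet regions).
    Spectral rules are absolute fractions.
    """
    th = thresholds or QualityThresholds()
    if th.neighborhood_radius < 1:
        raise ValueError("neighborhood radius must be >= 1")
    n_ch = features.p_low_rel.size
    with np.errstate(divide="ignore"):
        log_rms = np.log10(np.maximum(features.rms_channel, 1e-30))
    pos = {}
    for ch in range(grid.n_rows * grid.n_cols):
        if ch not in grid.missing:
            pos[ch] = grid.channel_position(ch)
    nb1 = {ch: [i for i in grid.neighbor_indices(*pos[ch], 1)
                if i not in grid.missing] for ch in range(n_ch)}
    nb_r = {ch: [i for i in grid.neighbor_indices(*pos[ch],
                                                  th.neighborhood_radius)
                 if i not in grid.missing] for ch in range(n_ch)}
    resid = np.array([log_rms[ch] - np.median(log_rms[nb1[ch]])
                      for ch in range(n_ch)])
    flags = np.zeros(n_ch, dtype=bool)
    rules: list[list[str]] = [[] for _ in range(n_ch)]
    for ch in range(n_ch):
        patch = nb_r[ch]
        mad = 1.4826 * np.median(np.abs(resid[patch] - np.median(resid[patch])))
        if abs(resid[ch]) / max(mad, th.mad_floor) > th.rms_z:
            rules[ch].append("rms")
        if features.p_low_rel[ch] > th.p_low_max:
            rules[ch].append("p_low")
        if features.p_line_rel[ch] > th.p_line_max:
            rules[ch].append("p_line")
        xc_med = np.median(features.neighbor_xcorr[patch])
        if xc_med - features.neighbor_xcorr[ch] > th.xcorr_drop:
            rules[ch].append("xcorr")
        flags[ch] = bool(rules[ch])
    return QualityReport(flags=flags, rules=rules, method="rules")


def ldof_scores(X: np.ndarray, k: int) -> np.ndarray:
    """Local distance-based outlier factor of each row of ``X``.

    LDOF(p) = (mean distance from p to its k nearest neighbors) /
    (mean pairwise distance among those k neighbors). Scores near 1 indicate
    points embedded in their neighborhood; large scores indicate outliers.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"need 1 <= k < n points (k={k}, n={n})")
    d = np.sqrt(np.maximum(
        ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1), 0.0))
    scores = np.empty(n)
    for i in range(n):
        order = np.argsort(d[i])
        nn = order[order != i][:k]
        dbar = d[i, nn].mean()
        inner = d[np.ix_(nn, nn)]
        Dbar = inner.sum() / (k * (k - 1)) if k > 1 else 0.0
        scores[i] = dbar / Dbar if Dbar > 0 else (0.0 if dbar == 0 else np.inf)
    return scores


def detect_outliers_ldof(features: ChannelFeatures, k: int = 10,
                         threshold: float = 2.0) -> QualityReport:
    """Unsupervised outlier detection: LDOF on the robustly standardized
    4-feature space, flagging channels with score above ``threshold``."""
    X = features.matrix()
    med = np.median(X, axis=0)
    mad = 1.4826 * np.median(np.abs(X - med), axis=0)
    Xs = (X - med) / np.maximum(mad, 1e-3)
    scores = ldof_scores(Xs, k)
    flags = scores > threshold
    rules = [["ldof"] if f else [] for f in flags]
    return QualityReport(flags=flags, rules=rules, method="ldof", scores=scores)


def replace_bad_channels(grid_values: np.ndarray, flags: np.ndarray,
                         *, tol: float = 1e-10, max_iter: int = 10_000
                         ) -> tuple[np.ndarray, dict]:
    """Repair flagged grid positions by interpolation of their neighbors.

    ``grid_values`` is (rows, cols) or (rows, cols, samples); ``flags`` a
    boolean (rows, cols) mask. Each bad position is replaced by the mean of
    its valid 8-connected neighbors; clusters of bad channels are relaxed
    iteratively (Jacobi) to a fixed point, so the operation is idempotent.
    Good channels are untouched.
    """
    v = np.array(grid_values, dtype=float, copy=True)
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != v.shape[:2]:
        raise ValueError("flags shape must match the grid shape")
    if flags.all():
        raise ValueError("cannot repair a grid whose channels are all flagged")
    if not flags.any():
        return v, {"repaired": [], "iterations": 0}
    rows, cols = flags.shape
    bad = list(zip(*np.nonzero(flags)))
    nbrs = {}
    for (r, c) in bad:
        nn = [(rr, cc) for rr in range(max(0, r - 1), min(rows, r + 2))
              for cc in range(max(0, c - 1), min(cols, c + 2))
              if (rr, cc) != (r, c)]
        nbrs[(r, c)] = nn

    # initialize bad cells from good neighbors, expanding through clusters
    filled = ~flags
    pending = set(bad)
    while pending:
        progressed = False
        for rc in sorted(pending):
            good = [p for p in nbrs[rc] if filled[p]]
            if good:
                v[rc] = np.mean([v[p] for p in good], axis=0)
                filled[rc] = True
                pending.discard(rc)
                progressed = True
        if not progressed:
            raise ValueError(f"bad channels {sorted(pending)} have no valid "
                             "neighbor to interpolate from")

    # relax to the harmonic fixed point: bad cell == mean of all its neighbors
    it = 0
    while it < max_iter:
        it += 1
        delta = 0.0
        new = {rc: np.mean([v[p] for p in nbrs[rc]], axis=0) for rc in bad}
        for rc, val in new.items():
            delta = max(delta, float(np.max(np.abs(val - v[rc]), initial=0.0)))
            v[rc] = val
        if delta <= tol:
            break
    else:
        raise RuntimeError("neighbor interpolation did not converge")
    return v, {"repaired": bad, "iterations": it}


def outlier_percent(n_flagged: int, n_total: int) -> int:
    """Flagged channels as a nearest-percent share of all recorded channels."""
    if n_total <= 0:
        raise ValueError("total channel count must be positive")
    return int(round(100.0 * n_flagged / n_total))
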