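"""Wavelet packet band features.

A J-level wavelet packet transform (WPT) splits a signal into ``2**J``
equal-width frequency nodes by recursively filtering with the analysis
pair (h, g) of an orthogonal wavelet (db4 here) and downsampling by two:

    d_j^{2i}[k]   = sum_n h[n] d_{j-1}^i[2k + L/2 - n]      (low-pass child)
    d_j^{2i+1}[k] = sum_n g[n] d_{j-1}^i[2k + L/2 - n]      (high-pass child)

with periodic boundary handling, which keeps the transform orthonormal
(Parseval holds exactly) and invertible.  The filter-bank ("natural")
node order is *not* the ascending frequency order: every high-pass
branch mirrors the spectrum of its subtree, so the frequency rank of a
natural index is its Gray code.  Band-limited signals (delta, theta,
alpha, beta) are recovered by zeroing all leaf nodes outside the band
and inverting the transform.

The per-epoch feature sequence stacks, channel-major, the original
signal and its four band reconstructions (8 channels x 5 streams = 40
streams), reduces each stream to an amplitude envelope by
root-mean-square pooling over fixed frame blocks, and (optionally)
standardizes each stream with statistics frozen on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view

from vims_eeg.recording import Epoch

__all__ = [
    "BandSpec", "DEFAULT_BANDS", "WaveletFilterPair", "WPTree",
    "wpt_decompose", "wpt_reconstruct", "reconstruct_band",
    "reconstruct_bands", "natural_to_frequency_order",
    "frequency_to_natural_order", "node_centre_hz",
    "extract_features", "stream_names", "FeatureScaler",
]


@dataclass(frozen=True)
class BandSpec:
    """A named half-open EEG frequency band [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"invalid band range [{self.low_hz}, {self.high_hz})")

    def contains(self, f: float) -> bool:
        return self.low_hz <= f < self.high_hz


#: Canonical EEG rhythm bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)


@dataclass
class WaveletFilterPair:
    """Analysis/synthesis filter quadruple of an orthogonal wavelet."""

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray

    @classmethod
    def from_name(cls, name: str = "db4") -> "WaveletFilterPair":
        w = pywt.Wavelet(name)
        return cls(name,
                   np.asarray(w.dec_lo), np.asarray(w.dec_hi),
                   np.asarray(w.rec_lo), np.asarray(w.rec_hi))

    @property
    def length(self) -> int:
        return len(self.dec_lo)


@dataclass
class WPTree:
    """Full wavelet packet tree of one 1-D signal.

    ``nodes[(j, i)]`` holds the coefficient array of node ``i`` (natural
    order, ``0 <= i < 2**j``) at level ``j``; level 0 node 0 is the
    (zero-padded) signal itself.
    """

    level: int
    fs: float
    orig_len: int
    padded_len: int
    filters: WaveletFilterPair
    nodes: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def leaf(self, i: int) -> np.ndarray:
        return self.nodes[(self.level, i)]

    @property
    def n_leaves(self) -> int:
        return 2 ** self.level


def _analysis_level(x: np.ndarray, filters: WaveletFilterPair):
    """One periodic analysis step applied row-wise.

    ``x`` has shape (n_nodes, N) with N even; returns (approx, detail)
    arrays of shape (n_nodes, N // 2), matching the periodization
    convention of standard wavelet packet implementations.
    """
    lo, hi = filters.dec_lo, filters.dec_hi
    L = filters.length
    n, N = x.shape
    if N % 2:
        raise ValueError("node length must be even")
    P = L // 2 - 1
    if P > 0:
        xe = np.concatenate([x[:, -P:], x, x[:, :P]], axis=1)
    else:
        xe = x
    win = sliding_window_view(xe, L, axis=1)[:, ::2, :]  # (n, N//2, L)
    return win @ lo[::-1], win @ hi[::-1]


def _synthesis_level(a: np.ndarray, d: np.ndarray, filters: WaveletFilterPair):
    """Inverse of :func:`_analysis_level` (row-wise, periodic)."""
    rlo, rhi = filters.rec_lo, filters.rec_hi
    L = filters.length
    n, Nh = a.shape
    N = 2 * Nh
    P = L // 2 - 1
    up = np.zeros((n, N + 2 * (L - 1)))
    up[:, L - 1:L - 1 + N:2] = a
    win = sliding_window_view(up, L, axis=1)
    c = win @ rlo[::-1]
    up[:] = 0.0
    up[:, L - 1:L - 1 + N:2] = d
    c = c + sliding_window_view(up, L, axis=1) @ rhi[::-1]
    # c is the full linear convolution (length N + L - 1); fold the
    # tails back periodically with the phase offset -(L/2 - 1).
    x = c[:, P:P + N].copy()
    if P > 0:
        x[:, N - P:] += c[:, :P]
    x[:, :P + 1] += c[:, N + P:]
    return x


def wpt_decompose(signal: np.ndarray, level: int,
                  filters: WaveletFilterPair | str = "db4",
                  fs: float = 500.0) -> WPTree:
    """Decompose a 1-D signal into a full wavelet packet tree.

    The signal is zero-padded at the end to the next multiple of
    ``2**level`` so that every node length divides evenly; the original
    length is retained for reconstruction.
    """
    if isinstance(filters, str):
        filters = WaveletFilterPair.from_name(filters)
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if level < 1:
        raise ValueError("level must be >= 1")
    if x.size < 2 ** level:
        raise ValueError(
            f"signal of {x.size} samples too short for level {level} "
            f"(needs >= {2 ** level})")
    block = 2 ** level
    padded = int(np.ceil(x.size / block)) * block
    xp = np.zeros(padded)
    xp[:x.size] = x

    tree = WPTree(level=level, fs=fs, orig_len=x.size,
                  padded_len=padded, filters=filters)
    tree.nodes[(0, 0)] = xp
    current = xp[None, :]
    for j in range(1, level + 1):
        a, d = _analysis_level(current, filters)
        nxt = np.empty((2 * current.shape[0], current.shape[1] // 2))
        nxt[0::2] = a
        nxt[1::2] = d
        for i in range(nxt.shape[0]):
            tree.nodes[(j, i)] = nxt[i]
        current = nxt
    return tree


def _invert_leaves(leaves: np.ndarray, filters: WaveletFilterPair) -> np.ndarray:
    """Invert stacked leaf arrays ``(batch, 2**J, N_J)`` to signals."""
    v = leaves
    while v.shape[1] > 1:
        b, n, N = v.shape
        a = v[:, 0::2, :].reshape(b * n // 2, N)
        d = v[:, 1::2, :].reshape(b * n // 2, N)
        v = _synthesis_level(a, d, filters).reshape(b, n // 2, 2 * N)
    return v[:, 0, :]


def wpt_reconstruct(tree: WPTree, keep: set[int] | None = None) -> np.ndarray:
    """Inverse WPT keeping only the natural-order leaf indices in ``keep``.

    ``keep=None`` keeps every node (perfect reconstruction).
    """
    n = tree.n_leaves
    leaves = np.stack([tree.leaf(i) for i in range(n)])
    if keep is not None:
        mask = np.zeros(n, dtype=bool)
        for i in keep:
            if not 0 <= i < n:
                raise IndexError(f"leaf index {i} out of range for level {tree.level}")
            mask[i] = True
        leaves = leaves * mask[:, None]
    out = _invert_leaves(leaves[None, :, :], tree.filters)[0]
    return out[:tree.orig_len]


def natural_to_frequency_order(level: int, natural_index: int) -> int:
    """Frequency rank (0 = lowest band) of a natural-order WPT node.

    Each high-pass split mirrors the spectrum of its subtree (the
    downsampled upper half-band is frequency-reversed), which staggers
    the filter-bank order: the natural index of the node with frequency
    rank ``r`` is the binary-reflected Gray code of ``r``, so the rank
    of a natural index is the *inverse* Gray code.
    """
    if not 0 <= natural_index < 2 ** level:
        raise IndexError(f"natural index {natural_index} out of range at level {level}")
    r = natural_index
    shift = 1
    while (natural_index >> shift) > 0:
        r ^= natural_index >> shift
        shift += 1
    return r


def frequency_to_natural_order(level: int, rank: int) -> int:
    """Natural-order index of the node with the given frequency rank."""
    if not 0 <= rank < 2 ** level:
        raise IndexError(f"rank {rank} out of range at level {level}")
    return rank ^ (rank >> 1)


def node_centre_hz(level: int, rank: int, fs: float) -> float:
    """Passband centre frequency of the node with frequency rank ``rank``."""
    width = (fs / 2.0) / 2 ** level
    return (rank + 0.5) * width


def _band_leaf_indices(level: int, band: BandSpec, fs: float) -> set[int]:
    idx = {frequency_to_natural_order(level, r)
           for r in range(2 ** level)
           if band.contains(node_centre_hz(level, r, fs))}
    if not idx:
        raise ValueError(
            f"band {band.name} [{band.low_hz}, {band.high_hz}) selects no "
            f"node at level {level}, fs {fs}")
    return idx


def reconstruct_band(tree: WPTree, band: BandSpec, fs: float | None = None
                     ) -> np.ndarray:
    """Band-limited signal: inverse WPT over nodes whose passband centre
    (in frequency order) lies in ``band``."""
    fs = tree.fs if fs is None else fs
    return wpt_reconstruct(tree, _band_leaf_indices(tree.level, band, fs))


def reconstruct_bands(tree: WPTree, bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                      fs: float | None = None) -> dict[str, np.ndarray]:
    """Reconstruct several bands in one batched inverse pass."""
    fs = tree.fs if fs is None else fs
    n = tree.n_leaves
    leaves = np.stack([tree.leaf(i) for i in range(n)])
    masks = np.zeros((len(bands), n))
    for b, band in enumerate(bands):
        for i in _band_leaf_indices(tree.level, band, fs):
            masks[b, i] = 1.0
    batch = leaves[None, :, :] * masks[:, :, None]
    out = _invert_leaves(batch, tree.filters)[:, :tree.orig_len]
    return {band.name: out[b] for b, band in enumerate(bands)}


# ---------------------------------------------------------------------------
# Feature sequences


def stream_names(channel_names, bands: tuple[BandSpec, ...] = DEFAULT_BANDS
                 ) -> list[str]:
    """Channel-major stream labels: ``<channel>_<orig|delta|...|beta>``."""
    tags = ["orig"] + [b.name for b in bands]
    return [f"{ch}_{tag}" for ch in channel_names for tag in tags]


def _rms_pool(x: np.ndarray, block: int) -> np.ndarray:
    n = (x.size // block) * block
    return np.sqrt(np.mean(x[:n].reshape(-1, block) ** 2, axis=1))


def extract_features(epoch: Epoch,
                     bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                     level: int = 8,
                     frames_per_second: float = 10.0,
                     wavelet: str = "db4",
                     scaler: "FeatureScaler | None" = None) -> np.ndarray:
    """Per-frame band-feature matrix of one epoch.

    Returns an array of shape ``(T, n_channels * (1 + len(bands)))`` with
    ``T = window_s * frames_per_second`` frames; each stream is the RMS
    envelope of the original signal or of one band reconstruction over
    consecutive frame blocks.  If ``scaler`` is given, streams are
    standardized with its stored statistics.
    """
    block = epoch.fs / frames_per_second
    if abs(block - round(block)) > 1e-9 or block < 1:
        raise ValueError(
            f"fs {epoch.fs} not divisible by frames_per_second {frames_per_second}")
    block = int(round(block))
    filters = WaveletFilterPair.from_name(wavelet)
    cols = []
    for ch in range(epoch.n_channels):
        sig = epoch.data[ch]
        tree = wpt_decompose(sig, level, filters, fs=epoch.fs)
        recs = reconstruct_bands(tree, bands)
        cols.append(_rms_pool(sig, block))
        for band in bands:
            cols.append(_rms_pool(recs[band.name], block))
    frames = np.column_stack(cols)
    if scaler is not None:
        frames = scaler.transform(frames)
    return frames


@dataclass
class FeatureScaler:
    """Per-stream standardization with statistics frozen on a training set."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, feature_list: list[np.ndarray]) -> "FeatureScaler":
        stacked = np.concatenate(feature_list, axis=0)
        self.mean = stacked.mean(axis=0)
        self.std = np.maximum(stacked.std(axis=0), 1e-12)
        return self

    def transform(self, frames: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("scaler not fitted")
        return (frames - self.mean) / self.std
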