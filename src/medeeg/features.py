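"""Feature extraction: CSP log-variance, STFT band power, and their fusion.

Three feature families feed the classifier:

* **CSP** — common spatial patterns: supervised spatial filters maximizing
  the variance ratio between the two classes, obtained by whitening the
  composite covariance and eigendecomposing the whitened class-A covariance.
  Features are the log of normalized variances of the filtered epoch.
* **STFT** — log band power (theta 4-8 Hz, alpha 8-13 Hz by default) from a
  short-time Fourier transform, averaged over time windows and over
  contiguous channel groups.
* **Fusion** — column-wise concatenation capped at 14 features; CSP features
  are always kept, STFT features are truncated by training-set variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochArray, FeatureTable

#: maximum fused feature count
FEATURE_CAP = 14

DEFAULT_BANDS = ((4.0, 8.0), (8.0, 13.0))
BAND_NAMES = {(4.0, 8.0): "theta", (8.0, 13.0): "alpha"}


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

@dataclass
class SpatialFilterBank:
    """CSP filter bank.

    ``W_full`` holds all ``n_channels`` filters (rows), sorted by descending
    class-A (meditation) eigenvalue; ``eigvals_A`` are those eigenvalues in
    [0, 1] (class-B eigenvalues are their complements).  ``W`` is the
    retained sub-bank: the top ``n_pairs`` and bottom ``n_pairs`` rows.
    """

    W_full: np.ndarray
    eigvals_A: np.ndarray
    n_pairs: int

    @property
    def W(self) -> np.ndarray:
        m = self.n_pairs
        return np.vstack([self.W_full[:m], self.W_full[-m:]])

    @property
    def n_channels(self) -> int:
        return self.W_full.shape[1]


def _mean_normalized_cov(data: np.ndarray) -> np.ndarray:
    """Mean over epochs of XX^T / trace(XX^T)."""
    covs = np.einsum("ecs,eds->ecd", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValueError("epoch with zero total variance")
    return (covs / traces[:, None, None]).mean(axis=0)


def fit_csp(epochs: EpochArray, n_pairs: int = 3,
            shrinkage: str | float = "auto") -> SpatialFilterBank:
    """Fit a CSP filter bank on labelled training epochs.

    Procedure: per-epoch trace-normalized spatial covariances are averaged
    per class (A = meditation, B = non-meditation); the composite C_A + C_B
    is whitened by its eigendecomposition; the whitened C_A is
    eigendecomposed and filters are sorted by descending class-A eigenvalue.
    Filter signs are fixed by making each row's largest-magnitude coefficient
    positive.

    ``shrinkage``: "auto" applies a fixed 1e-6 diagonal ridge only when the
    composite covariance condition number exceeds 1e10; a float applies that
    ridge unconditionally; 0 disables it.
    """
    n_ch = epochs.n_channels
    if n_ch < 2:
        raise ValueError("CSP needs at least 2 channels")
    if not (1 <= n_pairs <= n_ch // 2):
        raise ValueError("need 1 <= n_pairs <= n_channels/2")
    mask_a = epochs.labels == 1
    mask_b = epochs.labels == 0
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both classes must be present to fit CSP")
    c_a = _mean_normalized_cov(epochs.data[mask_a])
    c_b = _mean_normalized_cov(epochs.data[mask_b])
    c_c = c_a + c_b

    ridge = 0.0
    if shrinkage == "auto":
        if np.linalg.cond(c_c) > 1e10:
            ridge = 1e-6
    elif isinstance(shrinkage, (int, float)):
        ridge = float(shrinkage)
    else:
        raise ValueError("shrinkage must be 'auto' or a float")
    if ridge:
        c_c = c_c + ridge * np.eye(n_ch)

    evals, evecs = np.linalg.eigh(c_c)
    if evals[0] <= evals[-1] * 1e-12 or evals[0] <= 0:
        raise np.linalg.LinAlgError(
            "composite covariance is rank deficient; reduce the channel "
            "count or enable diagonal shrinkage (shrinkage=1e-6)"
        )
    whitener = (evecs / np.sqrt(evals)).T  # rows: whitening filters
    s_a = whitener @ c_a @ whitener.T
    d, v = np.linalg.eigh(s_a)
    order = np.argsort(d)[::-1]
    d = d[order]
    w_full = (v[:, order].T @ whitener)
    # sign convention: largest-|coefficient| positive in every row
    signs = np.sign(w_full[np.arange(n_ch), np.abs(w_full).argmax(axis=1)])
    signs[signs == 0] = 1.0
    w_full = w_full * signs[:, None]
    return SpatialFilterBank(W_full=w_full, eigvals_A=np.clip(d, 0.0, 1.0),
                             n_pairs=n_pairs)


def csp_features(epochs: EpochArray, bank: SpatialFilterBank) -> FeatureTable:
    """Log normalized-variance features from the retained CSP filters.

    feature_j = log(var_j / sum_k var_k) over the 2 * n_pairs retained
    filters; invariant to global scaling of the epoch signal.
    """
    if epochs.n_channels != bank.n_channels:
        raise ValueError("channel count mismatch between epochs and filter bank")
    w = bank.W
    proj = np.einsum("fc,ecs->efs", w, epochs.data)
    var = (proj**2).mean(axis=-1)  # epochs x filters
    total = var.sum(axis=1)
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        raise ValueError(f"zero projected variance in epoch(s) {bad.tolist()}")
    x = np.log(var / total[:, None])
    names = [f"csp{j:02d}" for j in range(w.shape[0])]
    return FeatureTable(X=x, labels=epochs.labels.copy(), feature_names=names)


# ---------------------------------------------------------------------------
# STFT band power
# ---------------------------------------------------------------------------

def channel_groups(n_channels: int, n_groups: int = 4) -> list[np.ndarray]:
    """Contiguous, near-equal channel blocks (anatomy-agnostic grouping)."""
    if not (1 <= n_groups <= n_channels):
        raise ValueError("need 1 <= n_groups <= n_channels")
    return list(np.array_split(np.arange(n_channels), n_groups))


def stft_band_power(epochs: EpochArray,
                    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
                    window_length: float = 1.0,
                    window_overlap: float = 0.5,
                    n_groups: int = 4) -> FeatureTable:
    """Log summed STFT power per band and contiguous channel group.

    Per epoch: Hann-tapered STFT with ``window_length`` s windows at
    ``window_overlap`` fractional overlap; power is summed over the band's
    frequency bins, averaged over time windows and over each channel group's
    channels, then log-transformed.  Features = |bands| x |groups|.
    """
    fs = epochs.fs
    nper = int(round(window_length * fs))
    if nper > epochs.data.shape[2]:
        raise ValueError("window_length exceeds epoch length")
    if not (0 <= window_overlap < 1):
        raise ValueError("window_overlap must be in [0, 1)")
    freqs, _, z = signal.stft(
        epochs.data, fs=fs, window="hann", nperseg=nper,
        noverlap=int(round(nper * window_overlap)), boundary=None,
        padded=False, axis=-1,
    )
    power = (np.abs(z) ** 2).mean(axis=-1)  # epochs x channels x freqs
    groups = channel_groups(epochs.n_channels, n_groups)
    cols, names = [], []
    for band in bands:
        low, high = band
        if not (0 < low < high < fs / 2):
            raise ValueError(f"band {band} outside (0, Nyquist)")
        mask = (freqs >= low) & (freqs < high)
        if not mask.any():
            df = fs / nper
            raise ValueError(
                f"band {band} Hz contains no STFT bins; window must be at "
                f"least {1.0 / (high - low):.3g} s (bin width {df:g} Hz)"
            )
        band_power = power[:, :, mask].sum(axis=-1)  # epochs x channels
        if np.any(band_power <= 0):
            raise ValueError("zero band power (all-zero epoch?)")
        bname = BAND_NAMES.get(band, f"{low:g}-{high:g}Hz")
        for gi, grp in enumerate(groups):
            cols.append(np.log(band_power[:, grp].mean(axis=1)))
            names.append(f"stft_{bname}_g{gi + 1}")
    return FeatureTable(X=np.column_stack(cols), labels=epochs.labels.copy(),
                        feature_names=names)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def stft_order_by_variance(table: FeatureTable) -> np.ndarray:
    """Column order by descending variance (label-free, deterministic).

    Ties broken by column index so the ranking is reproducible.
    """
    var = table.X.var(axis=0)
    return np.lexsort((np.arange(len(var)), -var))


def fuse(csp_table: FeatureTable, stft_table: FeatureTable,
         cap: int = FEATURE_CAP,
         stft_order: np.ndarray | None = None) -> FeatureTable:
    """Concatenate CSP and STFT features, truncating STFT columns to ``cap``.

    All CSP columns are always kept; if the total would exceed ``cap`` the
    STFT columns are kept in ``stft_order`` (default: descending
    training-set variance) until the cap is reached.  Pass the order computed
    on the *training* table when transforming test epochs.
    """
    if len(csp_table) != len(stft_table):
        raise ValueError("row count mismatch between CSP and STFT tables")
    if not np.array_equal(csp_table.labels, stft_table.labels):
        raise ValueError("label mismatch between CSP and STFT tables")
    if csp_table.n_features > cap:
        raise ValueError("CSP table alone exceeds the feature cap")
    room = cap - csp_table.n_features
    if stft_order is None:
        stft_order = stft_order_by_variance(stft_table)
    keep = np.sort(np.asarray(stft_order)[:room])
    x = np.hstack([csp_table.X, stft_table.X[:, keep]])
    names = csp_table.feature_names + [stft_table.feature_names[i] for i in keep]
    return FeatureTable(X=x, labels=csp_table.labels.copy(), feature_names=names)
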