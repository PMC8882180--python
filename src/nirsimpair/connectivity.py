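"""Sliding-window dynamic connectivity.

Pearson correlations of every channel pair over windows of fixed length
slid across the scan with a fixed skip, and their vectorization into the
ordered upper-triangle sequence fed to the recurrent classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "ConnectivitySequence",
    "n_windows",
    "sliding_window_correlations",
    "vectorize_windows",
    "matrix_from_vector",
]


def n_windows(T: int, window: int = 300, skip: int = 100) -> int:
    """Number of full windows: floor((T - window)/skip) + 1 for T >= window."""
    if T < window:
        return 0
    return (T - window) // skip + 1


@dataclass
class ConnectivitySequence:
    """Ordered sliding-window correlation matrices of one scan."""

    scan_key: tuple[str, str, int]
    window: int
    skip: int
    matrices: np.ndarray                  # (n_windows, C, C)
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]

    def validate(self) -> "ConnectivitySequence":
        M = self.matrices
        if not np.allclose(M, np.swapaxes(M, 1, 2), atol=1e-12):
            raise ValidationError("correlation matrices are not symmetric")
        if not np.allclose(np.diagonal(M, axis1=1, axis2=2), 1.0):
            raise ValidationError("correlation matrix diagonal is not 1")
        if np.any(M < -1 - 1e-12) or np.any(M > 1 + 1e-12):
            raise ValidationError("correlations outside [-1, 1]")
        return self


def sliding_window_correlations(hbo: np.ndarray, window: int = 300,
                                skip: int = 100,
                                scan_key: tuple[str, str, int] = ("", "", 1),
                                ) -> ConnectivitySequence:
    """Pearson correlation of every channel pair in each sliding window.

    ``hbo`` is (T, C).  Window starts are 0, skip, 2*skip, ... with
    start + window <= T; no partial final window.  Pairs involving a
    zero-variance channel get correlation 0, the diagonal stays 1, and the
    window is flagged degenerate.
    """
    X = np.asarray(hbo, float)
    T, C = X.shape
    if T < window:
        raise ValidationError(
            f"scan has {T} samples < window {window}; use a smaller window"
        )
    if skip < 1 or window < 2:
        raise ValidationError("window must be >= 2 and skip >= 1")
    starts = range(0, T - window + 1, skip)
    mats, degen = [], []
    for s in starts:
        seg = X[s: s + window]
        sd = seg.std(axis=0)
        # relative tolerance: a constant channel's sd is only ~1e-16 * |value|
        bad = sd <= 1e-12 * np.maximum(np.abs(seg).max(axis=0), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(seg, rowvar=False)
        if np.any(bad):
            R[bad, :] = 0.0
            R[:, bad] = 0.0
        np.fill_diagonal(R, 1.0)
        mats.append(np.clip(R, -1.0, 1.0))
        degen.append(bool(np.any(bad)))
    return ConnectivitySequence(
        scan_key=scan_key, window=window, skip=skip,
        matrices=np.array(mats), degenerate=np.array(degen, bool),
    ).validate()


def vectorize_windows(seq: ConnectivitySequence) -> np.ndarray:
    """Strict upper triangle of each window, row-major: (n_windows, C(C-1)/2).

    For 20 channels each vector has 190 entries, ordered (0,1), (0,2), ...,
    (0,19), (1,2), ...; the ordering is part of the public contract.
    """
    seq.validate()
    C = seq.n_channels
    iu = np.triu_indices(C, k=1)
    return seq.matrices[:, iu[0], iu[1]]


def matrix_from_vector(vec: np.ndarray, n_channels: int) -> np.ndarray:
    """Inverse of one row of :func:`vectorize_windows` (unit diagonal)."""
    expected = n_channels * (n_channels - 1) // 2
    if len(vec) != expected:
        raise ValidationError(
            f"vector length {len(vec)} != C(C-1)/2 = {expected}"
        )
    M = np.eye(n_channels)
    iu = np.triu_indices(n_channels, k=1)
    M[iu] = vec
    M[(iu[1], iu[0])] = vec
    return M
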