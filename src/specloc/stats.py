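"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["safe_pearson", "safe_pearson_rows"]

_EPS = 1e-12


def safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention.

    A vector with (numerically) zero variance carries no shape information,
    so its correlation with anything is defined as 0 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx < _EPS or sy < _EPS:
        return 0.0
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def safe_pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with the vector ``y``.

    Vectorized over rows; zero-variance rows (or a zero-variance ``y``)
    yield correlation 0.
    """
    rows = np.asarray(rows, dtype=float)
    y = np.asarray(y, dtype=float)
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sr = np.sqrt(np.einsum("ij,ij->i", rc, rc))
    sy = np.sqrt(yc @ yc)
    out = np.zeros(rows.shape[0])
    if sy < _EPS:
        return out
    ok = sr >= _EPS
    out[ok] = (rc[ok] @ yc) / (sr[ok] * sy)
    return np.clip(out, -1.0, 1.0)
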