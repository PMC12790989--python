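"""Small statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Ties and ordering are resolved by a stable sort on p-value so results are
    reproducible across runs. NaNs propagate.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    n = p.size
    if n == 0:
        return p.copy()
    adj = np.full(n, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        # enforce monotonicity from the largest p downwards
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.clip(ranked, 0.0, 1.0)
        adj[ok] = out
    return adj


def zscore(values: np.ndarray) -> np.ndarray:
    """Population z-scores ((x - mean) / sd with sd over n, not n-1).

    A constant vector maps to all zeros rather than NaN.
    """
    x = np.asarray(values, dtype=float)
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - mu) / sd
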