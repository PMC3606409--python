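"""Numba kernels for sliding-window order statistics.

The candidate scan needs linear-interpolated quartiles of every trailing
window ``x[j-w .. j]`` of a long trace, for ~30 window sizes.  No installed
library offers an O(n*w) exact sliding quantile with the linear
interpolation rule, so a sorted ring buffer is maintained in a jitted loop:
each slide removes the outgoing sample and inserts the incoming one by
binary search + shift.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _quartiles_from_sorted(buf, m, out, row):
    for t in range(3):
        h = 0.25 * (t + 1) * (m - 1)
        k = int(h)
        frac = h - k
        v = buf[k]
        if frac > 0.0 and k + 1 < m:
            v += frac * (buf[k + 1] - buf[k])
        out[row, t] = v


@njit(cache=True)
def trailing_quartiles(x, w):
    """Quartiles (0.25, 0.5, 0.75; linear interpolation) of x[j-w .. j]
    for every j >= w; rows j < w are NaN."""
    n = x.shape[0]
    m = w + 1
    out = np.full((n, 3), np.nan)
    if n < m:
        return out
    buf = np.sort(x[:m].copy())
    _quartiles_from_sorted(buf, m, out, w)
    for j in range(m, n):
        old = x[j - m]
        new = x[j]
        if new != old:
            i = np.searchsorted(buf, old)
            if new > old:
                while i + 1 < m and buf[i + 1] < new:
                    buf[i] = buf[i + 1]
                    i += 1
            else:
                while i > 0 and buf[i - 1] > new:
                    buf[i] = buf[i - 1]
                    i -= 1
            buf[i] = new
        _quartiles_from_sorted(buf, m, out, j)
    return out
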