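"""Sinusoidal positional encoding over time nodes.

The encoding marks the temporal position t of each row of a T x N ROI
time-series matrix using sine/cosine pairs over the brain-region axis:

    PE[t, 2n]   = sin(t / 10000^(2n/N))
    PE[t, 2n+1] = cos(t / 10000^(2n/N))

with t indexed from 0. Note the exponent is 2n/N where N is the number of
brain regions (feature columns), not the "d_model" convention of some
transformer variants. For odd N the final unpaired column uses the sine
formula. The encoding is added once to the raw input before the first
attention layer.
"""

from __future__ import annotations

import numpy as np


def positional_encoding(T: int, N: int) -> np.ndarray:
    """Return the T x N sinusoidal positional-encoding matrix.

    Parameters
    ----------
    T : int
        Number of time nodes (rows), >= 1.
    N : int
        Number of brain regions (columns), >= 1.

    Returns
    -------
    numpy.ndarray
        T x N matrix with every entry in [-1, 1]; depends only on (T, N).
    """
    if T < 1 or N < 1:
        raise ValueError(f"T and N must be positive, got T={T}, N={N}")
    t = np.arange(T, dtype=float)[:, None]          # T x 1
    even = np.arange(0, N, 2, dtype=float)          # the 2n column indices
    angles = t / np.power(10000.0, even / N)        # T x ceil(N/2)
    pe = np.empty((T, N), dtype=float)
    pe[:, 0::2] = np.sin(angles)
    # odd columns 2n+1 share the angle of their even partner 2n
    n_odd = N // 2
    pe[:, 1::2] = np.cos(angles[:, :n_odd])
    return pe


def add_positions(x: np.ndarray, pe: np.ndarray) -> np.ndarray:
    """Inject temporal position into an input matrix: elementwise x + PE.

    ``x`` may be a single T x N matrix or a batch (..., T, N); ``pe``
    broadcasts over leading axes.
    """
    x = np.asarray(x, dtype=float)
    pe = np.asarray(pe, dtype=float)
    if x.shape[-2:] != pe.shape:
        raise ValueError(
            f"shape mismatch: input trailing dims {x.shape[-2:]} vs PE {pe.shape}"
        )
    return x + pe
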