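"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


class UndefinedCorrelationError(ValueError):
    """Raised when a Pearson correlation is requested on zero-variance data."""


def pearson(x: np.ndarray, y: np.ndarray, *, context: str = "") -> float:
    """Pearson correlation of two 1-D arrays.

    Raises :class:`UndefinedCorrelationError` when either input has zero
    variance; ``context`` names the offending quantity in the message.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two 1-D arrays of equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        raise UndefinedCorrelationError(
            f"correlation undefined (zero variance){': ' + context if context else ''}"
        )
    return float((xc * yc).sum() / denom)


def spearman(x: np.ndarray, y: np.ndarray, *, context: str = "") -> float:
    """Spearman rank correlation, via Pearson on ranks."""
    from scipy.stats import rankdata

    return pearson(rankdata(x), rankdata(y), context=context)


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic generator for (seed, stream-key).

    Each operation draws from its own stream so adding trials to one
    generator does not perturb another's noise.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def condensed_upper(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (i<j) entries of a square matrix, row-major."""
    mat = np.asarray(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]
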