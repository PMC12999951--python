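"""Single-number skew index (SkewI) with the completeness/length QC filter.

The index scores how well the per-window GC-skew signs match an ideal
two-replichore pattern (+1 on one half of the windows, -1 on the other),
maximized over all circular rotations on the window grid; it lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_io import Completeness, Replicon
from .skew_core import windowed_skew

DEFAULT_SKEWI_WINDOW = 20_000
QC_MIN_LENGTH = 500_000


@dataclass(frozen=True)
class SkewIndexResult:
    replicon_id: str
    skewi: float
    window_size: int
    n_windows: int
    qc_pass: bool
    qc_reason: str


def max_rotation_agreement(signs: np.ndarray) -> float:
    """Max over circular rotations of |mean(sign * ideal pattern)|.

    The ideal pattern is +1 for the first floor(n/2) windows after rotation
    and -1 for the rest.  Zero signs contribute nothing.
    """
    signs = np.asarray(signs, dtype=np.int64)
    n = len(signs)
    if n < 2:
        raise ValueError("need at least 2 windows")
    half = n // 2
    total = signs.sum()
    doubled = np.concatenate([signs, signs])
    csum = np.concatenate([[0], np.cumsum(doubled)])
    r = np.arange(n)
    first_half = csum[r + half] - csum[r]
    # sum(s * p) = first_half - (total - first_half)
    scores = np.abs(2 * first_half - total) / n
    return float(scores.max())


def skew_index(
    replicon: Replicon, window_size: int = DEFAULT_SKEWI_WINDOW
) -> SkewIndexResult:
    """Compute SkewI for one replicon; QC is evaluated but never gates the value."""
    if replicon.length < 2 * window_size:
        raise ValueError(
            f"replicon {replicon.id!r} shorter than two windows "
            f"({replicon.length} < {2 * window_size})"
        )
    profile = windowed_skew(replicon, None, "total", window_size)
    signs = np.sign(profile.values).astype(np.int64)
    if not signs.any():
        warnings.warn(f"replicon {replicon.id!r}: all window skews are zero")
        value = 0.0
    else:
        value = max_rotation_agreement(signs)

    reasons = []
    if replicon.length < QC_MIN_LENGTH:
        reasons.append(f"length {replicon.length} < {QC_MIN_LENGTH}")
    if replicon.completeness is not Completeness.complete:
        reasons.append(f"completeness is {replicon.completeness.value!r}")
    return SkewIndexResult(
        replicon_id=replicon.id,
        skewi=value,
        window_size=window_size,
        n_windows=profile.n_windows,
        qc_pass=not reasons,
        qc_reason="; ".join(reasons) if reasons else "ok",
    )
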