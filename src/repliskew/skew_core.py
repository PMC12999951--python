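"""Windowed and cumulative GC skew plus the cumulative gene-strand-bias curve.

All profiles share a fixed-window grid: ``floor(length / window_size)``
complete windows, trailing partial window discarded.  The per-window skew is
``(G - C) / (G + C)`` over the positions of the requested class (total,
codon1/2/3 or noncoding); windows with no G or C in the class get skew 0 so
grids stay aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genome_io import PositionLabelMap, Replicon

SkewClass = Literal["total", "codon1", "codon2", "codon3", "noncoding"]

SKEW_CLASSES: tuple[SkewClass, ...] = ("total", "codon1", "codon2", "codon3", "noncoding")

DEFAULT_WINDOW_SIZE = 4096

_CLASS_TO_LABEL = {"codon1": 1, "codon2": 2, "codon3": 3, "noncoding": 0}


@dataclass(frozen=True)
class SkewProfile:
    replicon_id: str
    skew_class: SkewClass
    window_size: int
    values: np.ndarray
    g_counts: np.ndarray
    c_counts: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CumulativeProfile:
    replicon_id: str
    skew_class: SkewClass
    window_size: int
    cumulative: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.cumulative)


@dataclass(frozen=True)
class GSBProfile:
    """Cumulative gene-strand counter sampled at each window end.

    ``cumulative[k]`` is the per-position strand_cover prefix sum evaluated
    at position ``(k + 1) * window_size - 1``, so it is index-aligned with
    every CumulativeProfile of the same window size.
    """

    replicon_id: str
    window_size: int
    cumulative: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.cumulative)


def _n_windows(length: int, window_size: int) -> int:
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = length // window_size
    if n == 0:
        raise ValueError(
            f"no complete window: replicon length {length} < window size {window_size}"
        )
    return n


def _class_mask(labels: PositionLabelMap, skew_class: SkewClass, n_used: int) -> np.ndarray:
    if skew_class == "total":
        return np.ones(n_used, dtype=bool)
    want = _CLASS_TO_LABEL[skew_class]
    return np.asarray(labels.codon_label[:n_used]) == want


def windowed_skew(
    replicon: Replicon,
    labels: PositionLabelMap | None,
    skew_class: SkewClass = "total",
    window_size: int = DEFAULT_WINDOW_SIZE,
    gene_oriented: bool = False,
) -> SkewProfile:
    """Per-window (G - C)/(G + C) restricted to one position class.

    Counting is done on the reference (plus) strand by default.  With
    ``gene_oriented=True``, positions labelled by a minus-strand CDS have
    their base complemented before counting, i.e. the codon string as read
    on the coding strand is counted instead.
    """
    n = _n_windows(replicon.length, window_size)
    used = n * window_size
    seq = np.frombuffer(replicon.sequence[:used].encode(), dtype=np.uint8)
    if skew_class != "total" and labels is None:
        raise ValueError(f"class {skew_class!r} requires a PositionLabelMap")
    if labels is None:
        mask = np.ones(used, dtype=bool)
    else:
        if len(labels.codon_label) != replicon.length:
            raise ValueError("label map does not match replicon length")
        mask = _class_mask(labels, skew_class, used)

    is_g = seq == ord("G")
    is_c = seq == ord("C")
    if gene_oriented and labels is not None and skew_class != "total":
        flip = np.asarray(labels.label_strand[:used]) == -1
        is_g, is_c = np.where(flip, is_c, is_g), np.where(flip, is_g, is_c)

    g = (is_g & mask).reshape(n, window_size).sum(axis=1)
    c = (is_c & mask).reshape(n, window_size).sum(axis=1)
    denom = g + c
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    return SkewProfile(replicon.id, skew_class, window_size, values, g, c)


def cumulative_profile(profile: SkewProfile) -> CumulativeProfile:
    """Prefix-sum a windowed skew profile."""
    if profile.n_windows == 0:
        raise ValueError("empty profile")
    return CumulativeProfile(
        profile.replicon_id,
        profile.skew_class,
        profile.window_size,
        np.cumsum(profile.values),
    )


def gsb_profile(labels: PositionLabelMap, window_size: int = DEFAULT_WINDOW_SIZE) -> GSBProfile:
    """Cumulative gene-strand-bias counter sampled once per complete window."""
    n = _n_windows(len(labels.strand_cover), window_size)
    used = n * window_size
    per_window = (
        np.asarray(labels.strand_cover[:used], dtype=np.int64)
        .reshape(n, window_size)
        .sum(axis=1)
    )
    return GSBProfile(labels.replicon_id, window_size, np.cumsum(per_window))


def normalize_curve(curve: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Min-max scale a curve to [0, 1] and shift by ``offset`` (display only)."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    lo, hi = curve.min(), curve.max()
    if hi == lo:
        warnings.warn("constant curve cannot be min-max scaled; returning 0.5 + offset")
        return np.full_like(curve, 0.5 + offset)
    return (curve - lo) / (hi - lo) + offset


# ---------------------------------------------------------------------------
# profile TSV interchange


def profiles_to_frame(
    cumulative_by_class: dict[str, CumulativeProfile],
    skew_by_class: dict[str, SkewProfile],
) -> pd.DataFrame:
    rows = []
    for cls, cum in cumulative_by_class.items():
        prof = skew_by_class[cls]
        for i in range(cum.n_windows):
            rows.append(
                {
                    "replicon_id": cum.replicon_id,
                    "window_index": i,
                    "window_start": i * cum.window_size + 1,
                    "skew_class": cls,
                    "skew": prof.values[i],
                    "cumulative": cum.cumulative[i],
                }
            )
    return pd.DataFrame(rows)


def write_profiles_tsv(
    path: str | Path,
    cumulative_by_class: dict[str, CumulativeProfile],
    skew_by_class: dict[str, SkewProfile],
) -> None:
    frame = profiles_to_frame(cumulative_by_class, skew_by_class)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_profiles_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
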