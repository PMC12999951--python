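"""Correlation of GSB with CGC sub-skews, class aggregation and group tests.

Per replicon: Pearson correlation of the cumulative gene-strand-bias curve
against each cumulative skew curve (total, codon1/2/3, noncoding), all on
one window grid.  Across replicons: Table-style aggregation (mean, SD, CV%,
fraction of PCC > 0.5), single-strand G/C parity regression, and
nonparametric / parametric group comparisons with Holm-adjusted post-hocs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genome_io import FeatureTable, Replicon, build_position_labels
from .skew_core import (
    DEFAULT_WINDOW_SIZE,
    SKEW_CLASSES,
    cumulative_profile,
    gsb_profile,
    windowed_skew,
)

PCC_STATISTICS = ("pcc_total", "pcc_codon1", "pcc_codon2", "pcc_codon3", "pcc_noncoding")


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on zero variance instead of returning 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: an input has zero variance")
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationSet:
    replicon_id: str
    class_label: str = "other"
    pcc_total: float | None = None
    pcc_codon1: float | None = None
    pcc_codon2: float | None = None
    pcc_codon3: float | None = None
    pcc_noncoding: float | None = None

    def get(self, statistic: str) -> float | None:
        if statistic not in PCC_STATISTICS:
            raise KeyError(statistic)
        return getattr(self, statistic)


@dataclass(frozen=True)
class ClassSummary:
    class_label: str
    statistic: str
    mean: float
    sd: float | None
    cv_percent: float | None
    n: int
    frac_above_half: float


@dataclass(frozen=True)
class ParityFit:
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    trivial: bool = False


@dataclass(frozen=True)
class GroupComparison:
    method: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    group_centers: dict[str, float]
    posthoc: list[dict] = field(default_factory=list)


def replicon_correlation_set(
    replicon: Replicon,
    features: FeatureTable,
    window_size: int = DEFAULT_WINDOW_SIZE,
    class_label: str = "other",
    gene_oriented: bool = False,
) -> CorrelationSet:
    """PCC of the cumulative GSB curve against each cumulative sub-skew curve.

    A class whose cumulative curve is constant (e.g. no non-coding content)
    gets a missing PCC, not 0.
    """
    if replicon.length < 3 * window_size:
        raise ValueError("need at least 3 complete windows")
    labels = build_position_labels(replicon, features)
    gsb = gsb_profile(labels, window_size).cumulative.astype(float)
    pccs: dict[str, float | None] = {}
    for cls in SKEW_CLASSES:
        cum = cumulative_profile(
            windowed_skew(replicon, labels, cls, window_size, gene_oriented=gene_oriented)
        ).cumulative
        if np.ptp(cum) == 0 or np.ptp(gsb) == 0:
            pccs[f"pcc_{cls}"] = None
        else:
            pccs[f"pcc_{cls}"] = pearson(gsb, cum)
    return CorrelationSet(replicon.id, class_label, **pccs)


def aggregate_class(sets: list[CorrelationSet], statistic: str) -> ClassSummary:
    """Mean, sample SD, CV% (= 100*SD/|mean|) and fraction of PCC > 0.5."""
    if not sets:
        raise ValueError("empty list of correlation sets")
    labels = {s.class_label for s in sets}
    if len(labels) != 1:
        raise ValueError(f"expected a single class, got {sorted(labels)}")
    values = np.array([s.get(statistic) for s in sets if s.get(statistic) is not None])
    if values.size == 0:
        raise ValueError(f"no defined values for {statistic}")
    n = len(values)
    mean = float(values.mean())
    if n == 1:
        sd = cv = None
    else:
        sd = float(values.std(ddof=1))
        cv = float("inf") if mean == 0 else 100.0 * sd / abs(mean)
    return ClassSummary(
        class_label=labels.pop(),
        statistic=statistic,
        mean=mean,
        sd=sd,
        cv_percent=cv,
        n=n,
        frac_above_half=float((values > 0.5).mean()),
    )


def summaries_to_frame(summaries: list[ClassSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": s.class_label,
                "statistic": s.statistic,
                "mean": s.mean,
                "sd": s.sd,
                "cv_percent": s.cv_percent,
                "n": s.n,
                "pct_above_half": 100.0 * s.frac_above_half,
            }
            for s in summaries
        ]
    )


def chargaff_parity(replicons: list[Replicon]) -> ParityFit:
    """OLS of single-strand C totals on G totals across replicons (parity check)."""
    if len(replicons) < 2:
        raise ValueError("need at least 2 replicons")
    g = np.array([r.sequence.count("G") for r in replicons], dtype=float)
    c = np.array([r.sequence.count("C") for r in replicons], dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("degenerate fit: all G counts identical")
    res = sps.linregress(g, c)
    residuals = c - (res.intercept + res.slope * g)
    return ParityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residuals=residuals,
        trivial=len(replicons) == 2,
    )


def _posthoc_pairs(values_by_class: dict[str, np.ndarray], parametric: bool) -> list[dict]:
    pairs = list(combinations(sorted(values_by_class), 2))
    raw = []
    for a, b in pairs:
        if parametric:
            stat, p = sps.ttest_ind(values_by_class[a], values_by_class[b])
        else:
            stat, p = sps.mannwhitneyu(
                values_by_class[a], values_by_class[b], alternative="two-sided"
            )
        raw.append((a, b, float(stat), float(p)))
    adj = multipletests([r[3] for r in raw], method="holm")[1]
    return [
        {"group_a": a, "group_b": b, "statistic": s, "p_raw": p, "p_adjusted": float(q)}
        for (a, b, s, p), q in zip(raw, adj)
    ]


def compare_groups(values_by_class: dict[str, np.ndarray], method: str) -> GroupComparison:
    """Mann-Whitney (two groups), Kruskal-Wallis or one-way ANOVA (>= 2 groups).

    Omnibus tests are followed by all-pairs post-hocs with Holm adjustment.
    """
    if len(values_by_class) < 2:
        raise ValueError("need at least 2 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_class.items()}
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    arrays = list(groups.values())
    sizes = {k: len(v) for k, v in groups.items()}
    posthoc: list[dict] = []
    if method == "mann_whitney_two_tailed":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney requires exactly 2 groups")
        stat, p = sps.mannwhitneyu(*arrays, alternative="two-sided")
        centers = {k: float(np.median(v)) for k, v in groups.items()}
    elif method == "kruskal_wallis":
        stat, p = sps.kruskal(*arrays)
        centers = {k: float(np.median(v)) for k, v in groups.items()}
        posthoc = _posthoc_pairs(groups, parametric=False)
    elif method == "anova_oneway":
        stat, p = sps.f_oneway(*arrays)
        centers = {k: float(np.mean(v)) for k, v in groups.items()}
        posthoc = _posthoc_pairs(groups, parametric=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    if math.isnan(p):  # identical constant samples
        stat, p = 0.0, 1.0
    return GroupComparison(
        method=method,
        statistic=float(stat),
        p_value=float(p),
        group_sizes=sizes,
        group_centers=centers,
        posthoc=posthoc,
    )
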