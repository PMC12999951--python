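"""Two-segment piecewise-linear fit of the cumulative total GC skew.

The model, over circular window index x, is

    y(x) = c0 + drift * x + A * u(x; ori, ter)

where u is the unit triangle that rises linearly from 0 at ``ori`` to 1 at
``ter`` (arc length L1) and falls back to 0 over the complementary arc
(length L2 = n - L1).  The triangle is continuous at both breakpoints and
closed over the circle by construction; the drift term absorbs any net
genome-wide skew.  The predicted leading-strand fraction is div = L1 / n.

Breakpoints are found by exhaustive search over (ori, ter) pairs on the
window grid (coarsened to at most ``max_coarse`` candidate positions for
long profiles, then refined locally); slopes, drift and intercept are solved
by least squares at each pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Topology
from .skew_core import CumulativeProfile

DEFAULT_MAX_COARSE = 512


@dataclass(frozen=True)
class DivFit:
    replicon_id: str
    div: float
    ori_window: int
    ter_window: int
    slope_lead: float
    slope_lag: float
    drift: float
    rms_residual: float
    n_windows: int
    window_size: int
    note: str = ""

    @property
    def ori_bp(self) -> int:
        """1-based base-pair coordinate of the fitted origin breakpoint."""
        return self.ori_window * self.window_size + 1

    @property
    def ter_bp(self) -> int:
        return self.ter_window * self.window_size + 1


def _unit_triangle(n: int, ori: int, ter: int) -> np.ndarray:
    """Triangle rising 0->1 over the arc ori->ter, falling 1->0 over the rest."""
    x = np.arange(n)
    z = (x - ori) % n
    L1 = (ter - ori) % n
    L2 = n - L1
    return np.where(z <= L1, z / L1, (n - z) / L2)


def _batch_sse(y: np.ndarray, o: int, t_arr: np.ndarray):
    """Least-squares SSE of y ~ 1 + x + u(o, t) for every t in t_arr."""
    n = len(y)
    x = np.arange(n, dtype=float)
    z = (np.arange(n) - o) % n
    L1 = (t_arr - o) % n
    L2 = n - L1
    U = np.where(
        z[None, :] <= L1[:, None], z[None, :] / L1[:, None], (n - z)[None, :] / L2[:, None]
    )
    m = len(t_arr)
    Sx, Sxx, Sy, Sxy, Syy = x.sum(), (x * x).sum(), y.sum(), (x * y).sum(), (y * y).sum()
    Su = U.sum(axis=1)
    Suu = (U * U).sum(axis=1)
    Sxu = U @ x
    Suy = U @ y
    G = np.empty((m, 3, 3))
    G[:, 0, 0] = n
    G[:, 0, 1] = G[:, 1, 0] = Sx
    G[:, 0, 2] = G[:, 2, 0] = Su
    G[:, 1, 1] = Sxx
    G[:, 1, 2] = G[:, 2, 1] = Sxu
    G[:, 2, 2] = Suu
    G += 1e-12 * np.eye(3)
    rhs = np.stack([np.full(m, Sy), np.full(m, Sxy), Suy], axis=1)
    beta = np.linalg.solve(G, rhs[..., None])[..., 0]
    sse = Syy - (beta * rhs).sum(axis=1)
    return np.maximum(sse, 0.0), beta


def _search_pairs(y: np.ndarray, o_cand: np.ndarray, t_cand: np.ndarray):
    best = (np.inf, -1, -1, None)
    for o in o_cand:
        t_arr = t_cand[t_cand != o]
        if t_arr.size == 0:
            continue
        sse, beta = _batch_sse(y, int(o), t_arr)
        k = int(np.argmin(sse))
        if sse[k] < best[0]:
            best = (float(sse[k]), int(o), int(t_arr[k]), beta[k])
    return best


def fit_div(
    profile: CumulativeProfile,
    topology: Topology = Topology.circular,
    force_linear: bool = False,
    max_coarse: int = DEFAULT_MAX_COARSE,
) -> DivFit:
    """Fit the two-breakpoint replichore model to a cumulative total-skew curve."""
    if profile.skew_class != "total":
        raise ValueError("fit_div expects the total-skew cumulative profile")
    if topology is Topology.linear and not force_linear:
        raise ValueError(
            "replicon is linear; the replichore model presumes circular "
            "bidirectional replication (pass force_linear=True to override)"
        )
    y = np.asarray(profile.cumulative, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError(f"need at least 8 windows, got {n}")

    if n <= max_coarse:
        cand = np.arange(n)
        step = 1
    else:
        step = int(np.ceil(n / max_coarse))
        cand = np.arange(0, n, step)

    sse, o, t, beta = _search_pairs(y, cand, cand)

    if step > 1:
        # local refinement at full resolution around the coarse optimum
        o_loc = np.arange(o - step, o + step + 1) % n
        t_loc = np.arange(t - step, t + step + 1) % n
        sse2, o2, t2, beta2 = _search_pairs(y, np.unique(o_loc), np.unique(t_loc))
        if sse2 <= sse:
            sse, o, t, beta = sse2, o2, t2, beta2

    # exact re-solve at the winning pair (the search uses a tiny ridge)
    x = np.arange(n, dtype=float)
    M = np.column_stack([np.ones(n), x, _unit_triangle(n, o, t)])
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    sse = float(((M @ beta - y) ** 2).sum())

    c0, drift, amp = beta
    note = ""
    if amp < 0:
        # negative amplitude == the swapped pair with positive amplitude
        o, t = t, o
        amp = -amp
    L1 = (t - o) % n
    L2 = n - L1
    if amp == 0:
        note = "degenerate fit: zero amplitude"
    div = L1 / n
    if not (1 / n <= div <= 1 - 1 / n):
        note = (note + "; " if note else "") + "degenerate fit: div at grid edge"
    return DivFit(
        replicon_id=profile.replicon_id,
        div=float(div),
        ori_window=int(o),
        ter_window=int(t),
        slope_lead=float(amp / L1),
        slope_lag=float(-amp / L2),
        drift=float(drift),
        rms_residual=float(np.sqrt(sse / n)),
        n_windows=n,
        window_size=profile.window_size,
        note=note,
    )
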