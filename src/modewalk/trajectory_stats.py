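"""Dynamic characterization of trajectories and mode pools.

Time-averaged MSD with anomalous-exponent fitting, per-segment exponent
distributions, displacement probability densities (van Hove functions),
lag-resolved turning-angle histograms, the (turning-angle-difference,
radial-rate) phase space, successive-angle density maps and the zigzag
fraction.

Conventions: the MSD uses every (overlapping) start time within a track;
turning-angle statistics use non-overlapping displacement vectors on the
lag grid (t_n = n * lag).  Turning-angle differences are *not* re-wrapped
into [-pi, pi) — consecutive opposite full turns genuinely produce values
near +/-2 pi and the extended range preserves them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import FitError, NoDataError, RangeError, SizeError
from .features import turning_angles
from .tracks_io import Trajectory


@dataclass
class MSDCurve:
    """Time-averaged MSD per lag: msd(0) = 0, lags strictly increasing."""

    lags: np.ndarray      # minutes
    msd: np.ndarray       # um^2
    n_pairs: np.ndarray   # displacement pairs averaged per lag


@dataclass
class AngularSeries:
    """Turning angles, their unwrapped differences, and radial rates at one lag.

    thetas are signed angles in [-pi, pi); delta_thetas are raw successive
    differences theta_(n+1) - theta_n in (-2 pi, 2 pi); radial_rates are
    V_n = (|D(t_(n+1))| - |D(t_n)|) / lag in um/min, aligned with thetas.
    """

    lag: float
    thetas: np.ndarray
    delta_thetas: np.ndarray
    radial_rates: np.ndarray

    def phase_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(delta_theta, V) pairs where both are defined."""
        m = self.delta_thetas.size
        return self.delta_thetas, self.radial_rates[:m]


@dataclass
class DisplacementPDF:
    """Normalized 1D displacement density at one lag (unit integral)."""

    lag: float
    bin_edges: np.ndarray
    density: np.ndarray


def msd(traj: Trajectory, max_lag: float) -> MSDCurve:
    """Discrete time-averaged MSD over all overlapping start times.

    MSD(k) = (1/(N-k)) sum_i |r_(i+k) - r_i|^2 for integer sample lags k
    up to ``max_lag`` minutes (1-min sampling assumed post-preprocessing).
    At lag == duration a single displacement pair remains; beyond it no
    pair exists and the request is rejected.
    """
    if max_lag > traj.duration:
        raise RangeError("max_lag must not exceed the track duration")
    n = traj.n_points
    kmax = int(max_lag)
    lags = np.arange(kmax + 1, dtype=float)
    out = np.zeros(kmax + 1)
    pairs = np.zeros(kmax + 1, dtype=int)
    pairs[0] = n
    pos = traj.positions
    for k in range(1, kmax + 1):
        d = pos[k:] - pos[:-k]
        out[k] = np.mean(np.einsum("ij,ij->i", d, d))
        pairs[k] = n - k
    return MSDCurve(lags=lags, msd=out, n_pairs=pairs)


def fit_alpha(curve: MSDCurve, fit_lags: tuple[float, float] = (10.0, 30.0)) -> float:
    """Anomalous exponent: least-squares slope of log MSD vs log lag.

    Fitted over lags in [fit_lags[0], fit_lags[1]]; at least 3 lags with
    positive MSD are required.
    """
    lo, hi = fit_lags
    sel = (curve.lags >= lo) & (curve.lags <= hi) & (curve.lags > 0)
    if sel.sum() < 3:
        raise FitError("need at least 3 lags in the fit range")
    if np.any(curve.msd[sel] <= 0):
        raise FitError("MSD must be positive over the fit range")
    slope, *_ = sps.linregress(np.log(curve.lags[sel]), np.log(curve.msd[sel]))
    return float(slope)


@dataclass
class AlphaDistribution:
    """Per-segment anomalous exponents with summary quantiles."""

    alphas: np.ndarray
    quantiles: dict[str, float]


def alpha_distribution(
    segments: Iterable[Trajectory],
    fit_lags: tuple[float, float] = (10.0, 30.0),
    max_lag: float | None = None,
) -> AlphaDistribution:
    """Distribution P(alpha) of per-segment MSD exponents."""
    alphas = []
    for seg in segments:
        ml = max_lag if max_lag is not None else min(fit_lags[1], seg.duration - 1)
        alphas.append(fit_alpha(msd(seg, ml), fit_lags))
    arr = np.asarray(alphas)
    qs = {f"q{int(100 * q)}": float(np.quantile(arr, q)) for q in (0.25, 0.5, 0.75)}
    return AlphaDistribution(alphas=arr, quantiles=qs)


def displacement_pdf(
    trajs: Sequence[Trajectory],
    lag: float,
    bins: int | str | Sequence[float] = "fd",
) -> DisplacementPDF:
    """Van Hove density P(x | lag) of x-displacements over all start times.

    Pools every overlapping (t, t + lag) pair from every trajectory and
    normalizes the histogram to unit area (Freedman-Diaconis bins by
    default).
    """
    if not trajs:
        raise NoDataError("empty trajectory pool")
    k = int(lag)
    xs = []
    for tr in trajs:
        if lag >= tr.duration:
            raise RangeError("lag must be smaller than every track duration")
        xs.append(tr.positions[k:, 0] - tr.positions[:-k, 0])
    x = np.concatenate(xs)
    density, edges = np.histogram(x, bins=bins, density=True)
    return DisplacementPDF(lag=float(lag), bin_edges=edges, density=density)


@dataclass
class TurningAngleHeatmap:
    """Per-lag normalized angle distributions (each lag column sums to 1)."""

    lags: np.ndarray
    bin_edges: np.ndarray
    matrix: np.ndarray  # (n_bins, n_lags)


def turning_angle_heatmap(
    trajs: Sequence[Trajectory],
    lags: Sequence[int],
    n_bins: int = 61,
) -> TurningAngleHeatmap:
    """Signed-angle histograms per lag, pooled per angle over all trajectories."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    cols = []
    for lag in lags:
        if lag < 1:
            raise RangeError("lags must be >= 1 sample")
        pooled = [turning_angles(tr, lag=int(lag)) for tr in trajs]
        angles = np.concatenate([a for a in pooled if a.size] or [np.empty(0)])
        counts, _ = np.histogram(angles, bins=edges)
        total = counts.sum()
        cols.append(counts / total if total > 0 else np.zeros(n_bins))
    return TurningAngleHeatmap(lags=np.asarray(lags, dtype=float),
                               bin_edges=edges, matrix=np.column_stack(cols))


def phase_space(traj: Trajectory, lag: int = 1) -> AngularSeries:
    """Angular/radial series over non-overlapping displacement vectors.

    theta_n is the signed angle between D(t_n) and D(t_(n+1)); the
    difference delta theta_n = theta_(n+1) - theta_n is kept unwrapped;
    V_n = (|D(t_(n+1))| - |D(t_n)|) / lag.
    """
    k = int(lag)
    pts = traj.positions[::k]
    if pts.shape[0] < 4:
        raise SizeError("need >= 3 non-overlapping displacement vectors")
    disp = np.diff(pts, axis=0)
    lengths = np.linalg.norm(disp, axis=1)
    thetas = turning_angles(traj, lag=k)
    rates = (lengths[1:] - lengths[:-1]) / (k * 1.0)
    return AngularSeries(lag=float(k), thetas=thetas,
                         delta_thetas=np.diff(thetas), radial_rates=rates)


@dataclass
class SuccessiveAngles:
    """(theta_n, theta_(n+1)) pairs and their quadrant occupancy."""

    lag: float
    pairs: np.ndarray  # (M, 2)
    quadrant_counts: dict[str, int]


def successive_angle_density(traj: Trajectory, lag: int = 1) -> SuccessiveAngles:
    """Ordered successive-angle pairs for density mapping, with quadrant counts.

    Quadrants are counted over pairs with both angles nonzero: Q1 (+,+),
    Q2 (-,+), Q3 (-,-), Q4 (+,-).
    """
    thetas = turning_angles(traj, lag=int(lag))
    if thetas.size < 2:
        return SuccessiveAngles(lag=float(lag), pairs=np.empty((0, 2)),
                                quadrant_counts={q: 0 for q in ("Q1", "Q2", "Q3", "Q4")})
    pairs = np.column_stack((thetas[:-1], thetas[1:]))
    a, b = pairs[:, 0], pairs[:, 1]
    nz = (a != 0) & (b != 0)
    counts = {
        "Q1": int(((a > 0) & (b > 0) & nz).sum()),
        "Q2": int(((a < 0) & (b > 0) & nz).sum()),
        "Q3": int(((a < 0) & (b < 0) & nz).sum()),
        "Q4": int(((a > 0) & (b < 0) & nz).sum()),
    }
    return SuccessiveAngles(lag=float(lag), pairs=pairs, quadrant_counts=counts)


def zigzag_fraction(trajs: Trajectory | Sequence[Trajectory], lag: int = 1) -> float:
    """Ratio of opposite-sign to same-sign successive turning-angle pairs.

    Counts are pooled over the given trajectory or pool; pairs with either
    angle exactly zero are excluded.  Values above 1 indicate alternating
    (zigzag) turning, below 1 consistent-sign (curly) turning.  Returns
    +inf when no same-sign pair exists; raises :class:`NoDataError` when
    no valid pair exists at all.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    same = opposite = 0
    for tr in trajs:
        theta = turning_angles(tr, lag=int(lag))
        a, b = theta[:-1], theta[1:]
        valid = (a != 0) & (b != 0)
        prod = a[valid] * b[valid]
        same += int((prod > 0).sum())
        opposite += int((prod < 0).sum())
    if same + opposite == 0:
        raise NoDataError("no successive nonzero-angle pairs at this lag")
    if same == 0:
        return float("inf")
    return opposite / same
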