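"""Per-segment shape and motility descriptors.

Five features summarize each one-hour segment of a track:

* ``rg`` — radius of gyration, the square root of the trace of the
  gyration tensor (um); average spreading about the segment centroid.
* ``asphericity`` — normalized eigenvalue anisotropy of the gyration
  tensor, ((l1 - l2) / (l1 + l2))^2 in [0, 1]; 0 for an isotropic
  (circular) point cloud, 1 for collinear points.
* ``energy`` — mean squared step speed ((um/min)^2), a kinetic-energy
  proxy without the mass factor.
* ``rete`` — end-to-end distance between the first and last point (um).
* ``var_theta`` — population variance of the signed lag-1 turning angles
  (rad^2), counterclockwise positive.

All five are invariant under rigid translation and rotation; var_theta is
additionally reflection-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SizeError, UndefinedShapeError

FEATURE_NAMES = ("rg", "asphericity", "energy", "rete", "var_theta")


@dataclass(frozen=True)
class GyrationTensor:
    """Centered second-moment tensor of a segment's positions (um^2)."""

    rxx: float
    rxy: float
    ryy: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.rxx, self.rxy], [self.rxy, self.ryy]])

    @property
    def eigenvalues(self) -> tuple[float, float]:
        """(l1, l2) sorted descending; both >= 0 up to round-off."""
        lam = np.linalg.eigvalsh(self.matrix)
        return float(lam[1]), float(lam[0])

    @property
    def trace(self) -> float:
        return self.rxx + self.ryy


@dataclass(frozen=True)
class FeatureVector:
    rg: float
    asphericity: float
    energy: float
    rete: float
    var_theta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rg, self.asphericity, self.energy,
                         self.rete, self.var_theta])


def _positions(seg) -> np.ndarray:
    return np.asarray(seg.positions, dtype=float)


def _times(seg) -> np.ndarray:
    return np.asarray(seg.times, dtype=float)


def gyration_tensor(seg) -> GyrationTensor:
    """R_ij = (1/N) sum_l (r_i(t_l) - <r_i>)(r_j(t_l) - <r_j>).

    Equals half the mean pairwise squared-difference outer product
    (1/2N^2) sum_lm (r(t_l) - r(t_m))(r(t_l) - r(t_m))^T, which tests use
    as a brute-force oracle.
    """
    pos = _positions(seg)
    if pos.shape[0] < 2:
        raise SizeError("gyration tensor needs >= 2 points")
    c = pos - pos.mean(axis=0)
    t = c.T @ c / pos.shape[0]
    return GyrationTensor(rxx=float(t[0, 0]), rxy=float(t[0, 1]), ryy=float(t[1, 1]))


def radius_of_gyration(g: GyrationTensor) -> float:
    """sqrt(l1 + l2) = sqrt(Tr R), in um."""
    return float(np.sqrt(max(g.trace, 0.0)))


def asphericity(g: GyrationTensor) -> float:
    """((l1 - l2) / (l1 + l2))^2 in [0, 1]; undefined for a zero tensor."""
    l1, l2 = g.eigenvalues
    total = l1 + l2
    if total <= 0:
        raise UndefinedShapeError("asphericity undefined for a stationary segment")
    return float(((l1 - l2) / total) ** 2)


def energy(seg) -> float:
    """Mean squared step speed: (1/(N-1)) sum_n V_D(t_n)^2, (um/min)^2."""
    pos, t = _positions(seg), _times(seg)
    if pos.shape[0] < 2:
        raise SizeError("energy needs >= 2 points")
    v = np.linalg.norm(np.diff(pos, axis=0), axis=1) / np.diff(t)
    return float(np.mean(v ** 2))


def end_to_end(seg) -> float:
    """Euclidean distance from the first to the last point (um)."""
    pos = _positions(seg)
    if pos.shape[0] < 2:
        raise SizeError("end-to-end distance needs >= 2 points")
    return float(np.linalg.norm(pos[-1] - pos[0]))


def _signed_angles(vectors: np.ndarray) -> np.ndarray:
    """Signed angles in [-pi, pi) between consecutive 2D vectors.

    Sign from the 2D cross product (counterclockwise positive); exact
    reversals map to -pi by the half-open range convention.
    """
    a, b = vectors[:-1], vectors[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    theta = np.arctan2(cross, dot)
    theta[theta >= np.pi] = -np.pi  # arctan2 returns (-pi, pi]
    return theta


def turning_angles(seg, lag: int = 1) -> np.ndarray:
    """Signed turning angles between consecutive non-overlapping displacements.

    Displacement vectors are D(t_n) = r(t_(n+1) lag) - r(t_(n lag)) on the
    sample grid (t_n = n * lag), so vectors never overlap.  Zero-length
    displacements carry no direction and are skipped; angles are then
    formed between the surviving consecutive vectors.
    """
    pos = _positions(seg)
    if lag < 1:
        raise SizeError("lag must be >= 1 sample")
    pts = pos[::lag]
    if pts.shape[0] < 3:
        return np.empty(0)
    disp = np.diff(pts, axis=0)
    disp = disp[np.linalg.norm(disp, axis=1) > 0]
    if disp.shape[0] < 2:
        return np.empty(0)
    return _signed_angles(disp)


def var_theta(seg) -> float:
    """Population variance of the lag-1 signed turning angles (rad^2)."""
    pos = _positions(seg)
    if pos.shape[0] < 3:
        raise SizeError("turning-angle variance needs >= 3 points")
    theta = turning_angles(seg, lag=1)
    if theta.size == 0:
        return 0.0
    return float(np.var(theta))


def feature_vector(seg) -> FeatureVector:
    """Assemble all five descriptors for one segment."""
    g = gyration_tensor(seg)
    return FeatureVector(
        rg=radius_of_gyration(g),
        asphericity=asphericity(g),
        energy=energy(seg),
        rete=end_to_end(seg),
        var_theta=var_theta(seg),
    )


def feature_matrix(segments: Iterable) -> np.ndarray:
    """(n_segments, 5) array of feature vectors in FEATURE_NAMES order."""
    return np.array([feature_vector(s).as_array() for s in segments])


def features_frame(segments: Iterable) -> pd.DataFrame:
    """Tidy per-segment feature table with provenance columns."""
    rows = []
    for s in segments:
        fv = feature_vector(s)
        rows.append({
            "parent_id": getattr(s, "parent_id", getattr(s, "track_id", "")),
            "start_min": float(getattr(s, "start_min", _times(s)[0])),
            "end_min": float(getattr(s, "end_min", _times(s)[-1])),
            **{name: getattr(fv, name) for name in FEATURE_NAMES},
        })
    return pd.DataFrame(rows)
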