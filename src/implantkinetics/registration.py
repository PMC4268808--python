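"""Rigid alignment of implants across timepoints.

Two complementary registrations are provided:

* **Catheter-based** — iterative closest point (ICP) on the full in-target
  dwell clouds.  Because the fit aligns the clouds as well as possible, a
  shift of the whole implant is absorbed into the transform; the residuals
  measure *deformation* of the catheter configuration.
* **Marker-based** — closed-form quaternion (Horn) least-squares fit on the
  three fiducial markers, applied to the dwells.  Whole-implant shifts
  relative to the markers are *not* absorbed and show up in the field.

A Monte-Carlo routine quantifies how uncertainty in the marker coordinates
propagates into the marker-based dwell displacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .implant_model import MarkerSet, PairedDwells, PatientSeries, paired_dwells

__all__ = [
    "DegeneracyError",
    "RigidTransform",
    "RegistrationResult",
    "DisplacementField",
    "best_fit_rigid",
    "icp_register",
    "catheter_displacements",
    "marker_based_displacements",
    "marker_noise_uncertainty",
    "MarkerNoiseResult",
]

_ORTHO_TOL = 1e-9


class DegeneracyError(ValueError):
    """Point configuration insufficient to determine a rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R p + t`` (rotation then translation)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), mm

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a rigid registration.

    ``residuals`` are per-point 3-D offsets *after* alignment
    (matched target minus transformed source); ``rms_residual`` is the root
    mean square of their norms.
    """

    transform: RigidTransform
    residuals: np.ndarray  # (n, 3)
    rms_residual: float
    n_iterations: int
    converged: bool
    rms_history: tuple[float, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class DisplacementField:
    """Per-dwell shift vectors for one patient, interval and method.

    Components follow the package axis convention: ``dx`` L-R (+left),
    ``dy`` C-C (+caudal), ``dz`` D-V (+ventral).
    """

    patient_id: str
    interval: tuple[str, str]
    method: str  # "catheter_based" | "marker_based"
    keys: tuple[tuple[str, int], ...]
    vectors: np.ndarray  # (n, 3) mm

    @property
    def abs_mm(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def component(self, name: str) -> np.ndarray:
        idx = {"abs": None, "dx": 0, "dy": 1, "dz": 2}[name]
        return self.abs_mm if idx is None else self.vectors[:, idx]

    def __len__(self) -> int:
        return len(self.keys)


def _check_nondegenerate(points: np.ndarray, what: str) -> None:
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegeneracyError(f"{what}: need >= 3 points, got {pts.shape[0]}")
    centred = pts - pts.mean(axis=0)
    # rank < 2 of the centred cloud <=> all points on one line
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise DegeneracyError(f"{what}: points are collinear")


def best_fit_rigid(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping source onto target.

    Quaternion (Horn) absolute-orientation construction: subtract
    centroids, build the cross-covariance matrix, assemble the symmetric
    4x4 quaternion matrix and take its principal eigenvector.  The result
    is the global optimum of the summed squared residuals over all proper
    rigid transforms, for the given correspondences (row i of source
    corresponds to row i of target).
    """
    P = np.asarray(source_points, dtype=float)
    Q = np.asarray(target_points, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    _check_nondegenerate(P, "source")
    _check_nondegenerate(Q, "target")

    p_bar = P.mean(axis=0)
    q_bar = Q.mean(axis=0)
    M = (P - p_bar).T @ (Q - q_bar)  # cross-covariance

    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(N)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]  # unit quaternion

    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = q_bar - R @ p_bar
    return RigidTransform(R, t)


def register_known_correspondence(
    source_points: np.ndarray, target_points: np.ndarray
) -> RegistrationResult:
    """One-shot rigid fit with correspondences given by row order."""
    T = best_fit_rigid(source_points, target_points)
    residuals = np.asarray(target_points, float) - T.apply(source_points)
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RegistrationResult(T, residuals, rms, n_iterations=1, converged=True,
                              rms_history=(rms,))


def icp_register(
    source_points: np.ndarray,
    target_points: np.ndarray,
    max_iter: int = 100,
    tol_mm: float = 1e-6,
    matching: str = "nearest",
) -> RegistrationResult:
    """Iterative-closest-point rigid registration of two dwell clouds.

    Each iteration matches every (currently transformed) source point to
    its nearest target point, solves the closed-form rigid fit on those
    matches, and re-applies it from scratch.  The RMS residual is
    non-increasing across iterations (asserted on every run); iteration
    stops when the improvement drops below ``tol_mm`` or at ``max_iter``,
    in which case the result is flagged ``converged=False`` rather than
    raising.

    ``matching="known"`` bypasses nearest-neighbour matching and pairs by
    row order (requires equal-length clouds); this is the stronger oracle
    used to validate the nearest-neighbour path.

    Nearest-neighbour matching is not one-to-one: several source points may
    map to the same target point.
    """
    if matching == "known":
        return register_known_correspondence(source_points, target_points)
    if matching != "nearest":
        raise ValueError(f"unknown matching mode {matching!r}")

    P = np.asarray(source_points, dtype=float)
    Q = np.asarray(target_points, dtype=float)
    _check_nondegenerate(P, "source")
    _check_nondegenerate(Q, "target")

    tree = cKDTree(Q)
    transform = RigidTransform.identity()
    prev_rms = np.inf
    history: list[float] = []
    converged = False
    n_done = 0
    for n_done in range(1, max_iter + 1):
        moved = transform.apply(P)
        _, idx = tree.query(moved)
        matched = Q[idx]
        transform = best_fit_rigid(P, matched)
        residuals = matched - transform.apply(P)
        rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
        history.append(rms)
        # each half-step (re-match, re-fit) can only lower the SSE
        assert rms <= prev_rms + 1e-9, "ICP RMS increased between iterations"
        if prev_rms - rms < tol_mm:
            converged = True
            break
        prev_rms = rms

    moved = transform.apply(P)
    _, idx = tree.query(moved)
    residuals = Q[idx] - moved
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RegistrationResult(
        transform, residuals, rms, n_iterations=n_done, converged=converged,
        rms_history=tuple(history),
    )


def _interval_pair(series: PatientSeries, interval: tuple[str, str]) -> PairedDwells:
    scan_a, scan_b = interval
    return paired_dwells(series.snapshot(scan_a), series.snapshot(scan_b))


def catheter_displacements(
    series: PatientSeries,
    interval: tuple[str, str],
    max_iter: int = 100,
    tol_mm: float = 1e-6,
) -> DisplacementField:
    """Dwell displacements after ICP alignment of the later scan onto the earlier.

    The ICP transform is fitted on the full in-target clouds (nearest-
    neighbour matching, as clinically no correspondence would be assumed);
    the reported displacement of each corresponding (catheter, dwell) pair
    is ``T(b) - a``.  A rigid shift of the whole implant is absorbed by
    ``T`` and therefore invisible here.
    """
    pairs = _interval_pair(series, interval)
    scan_a, scan_b = interval
    cloud_a = series.snapshot(scan_a).in_target_points()
    cloud_b = series.snapshot(scan_b).in_target_points()
    result = icp_register(cloud_b, cloud_a, max_iter=max_iter, tol_mm=tol_mm)
    vectors = result.transform.apply(pairs.points_b) - pairs.points_a
    return DisplacementField(
        patient_id=series.patient_id,
        interval=interval,
        method="catheter_based",
        keys=pairs.keys,
        vectors=vectors,
    )


def _marker_transform(markers_a: MarkerSet, markers_b: MarkerSet) -> RigidTransform:
    return best_fit_rigid(markers_a.as_array(), markers_b.as_array())


def marker_based_displacements(
    series: PatientSeries, interval: tuple[str, str]
) -> DisplacementField:
    """Dwell displacements after marker-based rigid registration.

    The quaternion fit maps the earlier scan's three markers onto the later
    scan's; applying that transform to the earlier dwells predicts where a
    rigidly marker-locked implant would sit, and the displacement of each
    corresponding dwell is ``b - T(a)``.  Unlike the catheter-based method,
    motion of the implant relative to the markers is fully visible.
    """
    scan_a, scan_b = interval
    T = _marker_transform(
        series.snapshot(scan_a).markers, series.snapshot(scan_b).markers
    )
    pairs = _interval_pair(series, interval)
    vectors = pairs.points_b - T.apply(pairs.points_a)
    return DisplacementField(
        patient_id=series.patient_id,
        interval=interval,
        method="marker_based",
        keys=pairs.keys,
        vectors=vectors,
    )


@dataclass(frozen=True)
class MarkerNoiseResult:
    """Pooled marker-noise Monte-Carlo outcome, per axis (L-R, C-C, D-V)."""

    mean_mm: np.ndarray  # (3,)
    sd_mm: np.ndarray  # (3,)
    n_samples: int  # pooled dwell-level samples
    n_reps: int
    n_redraws: int
    replicate_means_mm: np.ndarray  # (n_patients * n_reps, 3) cluster means


def marker_noise_uncertainty(
    series_list: list[PatientSeries],
    noise_sd_mm: tuple[float, float, float] = (0.5, 1.0, 0.5),
    n_reps: int = 100,
    seed: int | None = None,
    interval: tuple[str, str] = ("CT1", "CT2"),
) -> MarkerNoiseResult:
    """Propagate marker-coordinate uncertainty into dwell displacements.

    For each patient and each of ``n_reps`` replicates, i.i.d. Gaussian
    noise with per-axis SDs ``noise_sd_mm`` (L-R, C-C, D-V) is added to all
    six marker coordinates of the interval, the marker-based registration is
    redone and applied to the dwells, and the dwell displacements are
    recorded *relative to the noise-free registration*.  Mean and SD per
    axis are pooled over replicates, dwells and patients.

    A replicate whose perturbed markers happen to be collinear is redrawn
    from the same random stream (counted in ``n_redraws``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sds = np.asarray(noise_sd_mm, dtype=float)
    if np.any(sds < 0):
        raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)

    deltas = []
    cluster_means = []
    n_redraws = 0
    scan_a, scan_b = interval
    for series in series_list:
        snap_a = series.snapshot(scan_a)
        snap_b = series.snapshot(scan_b)
        pairs = paired_dwells(snap_a, snap_b)
        A, B = snap_a.markers.as_array(), snap_b.markers.as_array()
        base_pred = best_fit_rigid(A, B).apply(pairs.points_a)
        for _ in range(n_reps):
            while True:
                try:
                    An = MarkerSet.from_array(A + rng.normal(0.0, sds, size=(3, 3)))
                    Bn = MarkerSet.from_array(B + rng.normal(0.0, sds, size=(3, 3)))
                    T = best_fit_rigid(An.as_array(), Bn.as_array())
                except (DegeneracyError, ValueError):
                    n_redraws += 1
                    warnings.warn("collinear perturbed markers; replicate redrawn")
                    continue
                break
            delta = T.apply(pairs.points_a) - base_pred
            deltas.append(delta)
            cluster_means.append(delta.mean(axis=0))

    pooled = np.concatenate(deltas, axis=0)
    return MarkerNoiseResult(
        mean_mm=pooled.mean(axis=0),
        sd_mm=pooled.std(axis=0, ddof=1),
        n_samples=pooled.shape[0],
        n_reps=n_reps,
        n_redraws=n_redraws,
        replicate_means_mm=np.stack(cluster_means),
    )
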