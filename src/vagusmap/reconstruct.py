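"""Tikhonov inversion, noise-normalized images and center-of-mass localization.

The measurement model is linear: dv = J x with x the per-voxel fractional
conductivity change.  Images are produced by 0th-order Tikhonov
regularization, x = (J'J + lambda^2 I)^{-1} J' dv, with lambda tied to a
fixed measurement-noise amplitude eps (1 uV for evoked dV, 10 nV for
spontaneous dV-RMS): lambda = eps * s1 / s_mean, scaled to the singular
spectrum of J so residuals at the noise floor are not fit.

The noise-based voxel correction converts the raw solution into a Z-score
map: each voxel is divided by its noise-propagation scale, eps times the
norm of the corresponding row of the regularized inverse, so under pure
measurement noise of RMS eps every voxel has unit standard deviation.
Peak activity is localized as the intensity-weighted center of mass of the
16 highest-|Z| voxels (~5% of the ~340-voxel grid) at the time of the
signal peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import JacobianMatrix


class ReconstructionError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReconstructionConfig:
    """Inversion settings; ``noise_amplitude`` is in volts."""

    noise_amplitude: float = 1e-6      # 1 uV evoked; use 10e-9 for dV-RMS
    top_k: int = 16
    lambda_scale: float = 1.0          # multiplier on the default lambda rule

    def __post_init__(self) -> None:
        if self.noise_amplitude <= 0:
            raise ValueError("noise amplitude must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class EITImage:
    """Z-scored conductivity-change map over the voxel grid."""

    z: np.ndarray                 # (n_voxels,) dimensionless
    grid: "np.ndarray"            # (n_voxels, 2) voxel centers, meters
    peak_time: float | None = None
    branch: str = ""


@dataclass
class CoMRecord:
    """Localized functional/structural center for one organ and technique."""

    x_um: float
    y_um: float
    organ: str
    technique: str                # eit | ss | microct
    animal: str = ""
    level: str = ""

    @property
    def radius_um(self) -> float:
        return float(np.hypot(self.x_um, self.y_um))

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.y_um, self.x_um)) % 360.0)

    @classmethod
    def from_polar(cls, radius_um: float, angle_deg: float, organ: str,
                   technique: str, animal: str = "", level: str = "") -> "CoMRecord":
        a = np.radians(angle_deg)
        return cls(x_um=radius_um * np.cos(a), y_um=radius_um * np.sin(a),
                   organ=organ, technique=technique, animal=animal, level=level)


class TikhonovInverter:
    """Regularized inverse of a voxel Jacobian for a fixed kept-row set.

    Excluded measurements are handled by row deletion; the inverse is built
    once (SVD) and applied to any number of measurement vectors or
    matrices (voxels x time).
    """

    def __init__(self, jacobian: JacobianMatrix, kept: np.ndarray | None = None,
                 config: ReconstructionConfig | None = None):
        self.config = config or ReconstructionConfig()
        self.grid = jacobian.grid
        J = jacobian.matrix
        if kept is not None:
            kept = np.asarray(kept, dtype=bool)
            if kept.shape[0] != J.shape[0]:
                raise ValueError("kept mask length != measurement count")
            J = J[kept]
        if J.shape[0] == 0:
            raise ReconstructionError("empty measurement set")
        self.kept = kept
        self._J = J
        U, s, Vt = np.linalg.svd(J, full_matrices=False)
        eps = self.config.noise_amplitude
        s_pos = s[s > 0]
        self.lam = self.config.lambda_scale * eps * s_pos[0] / s_pos.mean()
        filt = s / (s ** 2 + self.lam ** 2)
        self._M = (Vt.T * filt) @ U.T                 # (n_voxels, n_meas)
        # voxels with no sensitivity at all (empty columns) get an exactly
        # zero inverse row so their Z-score is defined as 0
        dead = np.linalg.norm(J, axis=0) == 0
        self._M[dead] = 0.0
        self.row_norms = np.linalg.norm(self._M, axis=1)

    def invert(self, dv: np.ndarray) -> np.ndarray:
        """Solve for per-voxel fractional conductivity change.

        ``dv`` in volts, shape (n_meas,) or (n_meas, n_times), already
        restricted to the kept rows.
        """
        dv = np.asarray(dv, dtype=float)
        if dv.shape[0] != self._M.shape[1]:
            raise ValueError("measurement vector length != kept row count")
        return self._M @ dv

    def z_score(self, x: np.ndarray) -> np.ndarray:
        """Noise-based voxel correction: value / (eps * row norm).

        Voxels with zero sensitivity (empty columns) are set to 0.
        """
        x = np.asarray(x, dtype=float)
        eps = self.config.noise_amplitude
        scale = eps * self.row_norms
        safe = np.where(scale > 0, scale, 1.0)
        if x.ndim == 1:
            return np.where(scale > 0, x / safe, 0.0)
        return np.where((scale > 0)[:, None], x / safe[:, None], 0.0)


def tikhonov_invert(jacobian: JacobianMatrix, dv: np.ndarray,
                    kept: np.ndarray | None = None,
                    config: ReconstructionConfig | None = None) -> np.ndarray:
    """One-shot regularized inversion (see TikhonovInverter)."""
    return TikhonovInverter(jacobian, kept, config).invert(dv)


def noise_correct(jacobian: JacobianMatrix, dv: np.ndarray,
                  kept: np.ndarray | None = None,
                  config: ReconstructionConfig | None = None,
                  branch: str = "") -> EITImage:
    """Invert and Z-score a measurement vector into an EITImage."""
    inv = TikhonovInverter(jacobian, kept, config)
    z = inv.z_score(inv.invert(dv))
    return EITImage(z=z, grid=jacobian.grid.centers, branch=branch)


def find_peak_time(z_sequence: np.ndarray, times: np.ndarray,
                   window: tuple[float, float] | None = None) -> float:
    """Time at which the maximum |Z| over voxels peaks.

    ``z_sequence`` is (n_voxels, n_times).  Ties return the earliest time;
    for evoked data, ``window`` restricts the search to the post-latency
    interval.
    """
    z = np.atleast_2d(z_sequence)
    times = np.asarray(times, dtype=float)
    if z.shape[1] != times.size:
        raise ValueError("time axis does not match image sequence")
    mask = np.ones(times.size, dtype=bool)
    if window is not None:
        mask = (times >= window[0]) & (times <= window[1])
        if not mask.any():
            raise ValueError("peak window excludes all samples")
    prof = np.abs(z[:, mask]).max(axis=0)
    return float(times[mask][int(np.argmax(prof))])


def com_top_voxels(image: EITImage, k: int = 16) -> CoMRecord:
    """Intensity-weighted center of mass of the k highest-|Z| voxels.

    Ties at the k-th rank are broken in favor of voxels nearer the image
    centroid (stable, documented tie rule).
    """
    z = np.abs(np.asarray(image.z, dtype=float))
    if k > z.size:
        raise ValueError("k exceeds voxel count")
    if not np.any(z > 0):
        raise ReconstructionError("no activity: image is identically zero")
    centroid = image.grid.mean(axis=0)
    dist = np.hypot(*(image.grid - centroid).T)
    order = np.lexsort((dist, -z))      # primary: |Z| desc; tie: nearer first
    top = order[:k]
    w = z[top]
    com = (image.grid[top] * w[:, None]).sum(axis=0) / w.sum()
    return CoMRecord(x_um=com[0] * 1e6, y_um=com[1] * 1e6,
                     organ=image.branch, technique="eit")
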