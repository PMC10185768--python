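"""Co-registration of microCT, EIT and selective-stimulation centers.

MicroCT cross-sections are not perfectly circular, while EIT images and
selective-stimulation loci live on an idealized circular cuff geometry.
Co-registration therefore (a) deforms each microCT fascicle table into the
circular frame — rotation plus independent X/Y axis scaling only, no shear
— with the cuff opening re-anchored to 90 degrees; (b) quantifies EIT
localization error against microCT as a Cartesian distance split into
radial and angular components; and (c) clusterizes center-of-mass sets
across animals by per-animal rigid rotations that minimize total
within-cluster dispersion, finally rotating the ensemble so the laryngeal
centroid sits at 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import CUFF_OPENING_DEG, wrap_deg
from .reconstruct import CoMRecord


class CoregistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EllipseOutline:
    """Nerve-outline ellipse: center (um), semi-axes a/b (um), axis tilt."""

    cx: float
    cy: float
    a: float
    b: float
    phi_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


def fit_ellipse(points_um: np.ndarray) -> EllipseOutline:
    """Least-squares ellipse fit to outline points (x, y in um)."""
    from skimage.measure import EllipseModel

    model = EllipseModel()
    if not model.estimate(np.asarray(points_um, dtype=float)):
        raise CoregistrationError("degenerate outline; ellipse fit failed")
    cx, cy, a, b, theta = model.params
    if a < b:                      # normalize: a is the major axis
        a, b, theta = b, a, theta + np.pi / 2
    return EllipseOutline(cx=cx, cy=cy, a=a, b=b,
                          phi_deg=float(np.degrees(theta) % 180.0))


@dataclass
class FascicleTable:
    """Per-fascicle centers (um) with organ labels on one cross-section."""

    table: pd.DataFrame            # columns x_um, y_um, organ, animal, level
    outline: EllipseOutline
    cuff_opening_deg: float
    nerve_radius_um: float

    def points(self) -> np.ndarray:
        return self.table[["x_um", "y_um"]].to_numpy(dtype=float)


@dataclass(frozen=True)
class AlignmentTransform:
    """Rigid deformation: rotation, axis-aligned scaling, rotation, shift.

    Applied as p' = R(post_rotation) S R(rotation) (p - translation); the
    scaling acts only along the intermediate X/Y axes (no shear).
    """

    rotation: float                # degrees, pre-scaling
    sx: float
    sy: float
    post_rotation: float = 0.0     # degrees
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("axis scale factors must be positive")

    def _mats(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        def rot(d: float) -> np.ndarray:
            c, s = np.cos(np.radians(d)), np.sin(np.radians(d))
            return np.array([[c, -s], [s, c]])
        return rot(self.rotation), np.diag([self.sx, self.sy]), rot(self.post_rotation)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        R1, S, R2 = self._mats()
        return (R2 @ S @ R1 @ (np.asarray(pts, dtype=float) - self.translation).T).T

    def inverse_apply(self, pts: np.ndarray) -> np.ndarray:
        R1, S, R2 = self._mats()
        M = np.linalg.inv(R2 @ S @ R1)
        return (M @ np.asarray(pts, dtype=float).T).T + self.translation


def microct_com(fascicles: FascicleTable, organ: str, animal: str = "",
                level: str = "") -> CoMRecord:
    """Unweighted mean of one organ's fascicle centers."""
    sub = fascicles.table[fascicles.table.organ == organ]
    if sub.empty:
        raise CoregistrationError(f"organ {organ!r} absent from fascicle table")
    return CoMRecord(x_um=float(sub.x_um.mean()), y_um=float(sub.y_um.mean()),
                     organ=organ, technique="microct",
                     animal=animal or str(sub.animal.iloc[0]),
                     level=level or str(sub.level.iloc[0]))


def ellipse_to_circle(fascicles: FascicleTable,
                      cuff_opening_deg: float | None = None
                      ) -> tuple[FascicleTable, AlignmentTransform]:
    """Deform an elliptical cross-section into the circular cuff frame.

    Steps: center on the outline, rotate the ellipse axes onto X/Y, scale
    each axis to the nerve radius, then rotate so the cuff-opening landmark
    sits at 90 degrees.  Relative angular order of fascicles is preserved
    (both scale factors are positive).
    """
    out = fascicles.outline
    opening = fascicles.cuff_opening_deg if cuff_opening_deg is None \
        else cuff_opening_deg
    R = fascicles.nerve_radius_um
    pre = AlignmentTransform(rotation=-out.phi_deg, sx=R / out.a, sy=R / out.b,
                             translation=np.array([out.cx, out.cy]))
    u = np.array([np.cos(np.radians(opening)), np.sin(np.radians(opening))])
    u2 = pre.apply(u[None] + pre.translation)[0]
    post = CUFF_OPENING_DEG - np.degrees(np.arctan2(u2[1], u2[0]))
    tf = AlignmentTransform(rotation=-out.phi_deg, sx=R / out.a, sy=R / out.b,
                            post_rotation=post,
                            translation=np.array([out.cx, out.cy]))
    pts = tf.apply(fascicles.points())
    new = fascicles.table.copy()
    new["x_um"], new["y_um"] = pts[:, 0], pts[:, 1]
    circ = FascicleTable(table=new,
                         outline=EllipseOutline(0.0, 0.0, R, R, 0.0),
                         cuff_opening_deg=CUFF_OPENING_DEG,
                         nerve_radius_um=R)
    return circ, tf


@dataclass
class ErrorDecomposition:
    cartesian_um: float
    radial_um: float
    angular_deg: float             # wrapped to [0, 180]


def com_error(a: CoMRecord, b: CoMRecord) -> ErrorDecomposition:
    """Cartesian distance and its radial/angular split between two CoMs."""
    cart = float(np.hypot(a.x_um - b.x_um, a.y_um - b.y_um))
    radial = float(abs(a.radius_um - b.radius_um))
    ang = float(abs(wrap_deg(a.angle_deg - b.angle_deg)))
    return ErrorDecomposition(cartesian_um=cart, radial_um=radial,
                              angular_deg=ang)


def angular_separation(coms: dict[str, CoMRecord]) -> dict[str, float]:
    """Pulmonary and cardiac angular distances from the laryngeal CoM, in
    degrees; signed values are wrapped to (-180, 180] and reported as
    magnitudes."""
    for organ in ("laryngeal", "pulmonary", "cardiac"):
        if organ not in coms:
            raise CoregistrationError(f"missing organ {organ!r}")
    lar = coms["laryngeal"].angle_deg
    return {
        organ: float(abs(wrap_deg(coms[organ].angle_deg - lar)))
        for organ in ("pulmonary", "cardiac")
    }


@dataclass
class ClusterizationResult:
    rotations_deg: dict[str, float]            # per animal
    centroids_um: dict[str, np.ndarray]        # per organ
    member_distances_um: pd.DataFrame          # animal, organ, distance
    mean_dispersion_um: float
    rotated: dict[str, dict[str, CoMRecord]]   # animal -> organ -> CoM


def _rotate_xy(pts: np.ndarray, deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return (np.array([[c, -s], [s, c]]) @ np.asarray(pts, dtype=float).T).T


def _objective(points: dict[str, dict[str, np.ndarray]]) -> float:
    """Sum over organs of the mean distance of animal CoMs to the organ
    centroid."""
    organs = next(iter(points.values())).keys()
    total = 0.0
    for organ in organs:
        P = np.stack([points[a][organ] for a in points])
        c = P.mean(axis=0)
        total += float(np.hypot(*(P - c).T).mean())
    return total


def clusterize(com_sets: dict[str, dict[str, CoMRecord]],
               grid_deg: float = 1.0, max_sweeps: int = 50
               ) -> ClusterizationResult:
    """Cross-animal clusterization by per-animal rigid rotation search.

    Coordinate descent over animals: each animal's rotation is optimized on
    an exhaustive grid (default 1 degree) holding the others fixed, cycling
    until no improvement; deterministic, initialized at identity.  The
    relative CoM geometry within each animal is preserved by construction.
    Afterward the whole ensemble is rotated so the laryngeal cluster
    centroid sits at 90 degrees (the cuff-opening reference).
    """
    animals = sorted(com_sets)
    if len(animals) < 2:
        raise CoregistrationError("clusterization needs at least 2 animals")
    organs = sorted(next(iter(com_sets.values())))
    for a in animals:
        if sorted(com_sets[a]) != organs:
            raise CoregistrationError(f"animal {a!r} missing organs")
    base = {a: {o: np.array([com_sets[a][o].x_um, com_sets[a][o].y_um])
                for o in organs} for a in animals}
    rot = {a: 0.0 for a in animals}
    grid = np.arange(0.0, 360.0, grid_deg)

    def rotated_points() -> dict[str, dict[str, np.ndarray]]:
        return {a: {o: _rotate_xy(base[a][o][None], rot[a])[0] for o in organs}
                for a in animals}

    best = _objective(rotated_points())
    for _ in range(max_sweeps):
        improved = False
        for a in animals:
            others = {x: {o: _rotate_xy(base[x][o][None], rot[x])[0]
                          for o in organs} for x in animals if x != a}
            P = np.stack([base[a][o] for o in organs])         # (O, 2)
            cand = np.einsum("gij,oj->goi", np.stack([
                np.array([[np.cos(np.radians(g)), -np.sin(np.radians(g))],
                          [np.sin(np.radians(g)), np.cos(np.radians(g))]])
                for g in grid]), P)                            # (G, O, 2)
            obj = np.zeros(grid.size)
            for oi, o in enumerate(organs):
                Q = np.stack([others[x][o] for x in others]) if others else \
                    np.zeros((0, 2))
                allpts = np.concatenate([Q[None].repeat(grid.size, 0),
                                         cand[:, oi:oi + 1]], axis=1)
                c = allpts.mean(axis=1, keepdims=True)
                obj += np.hypot(*(allpts - c).transpose(2, 0, 1)).mean(axis=1)
            gi = int(np.argmin(obj))
            if obj[gi] + 1e-12 < best:
                rot[a] = float(grid[gi])
                best = obj[gi]
                improved = True
        if not improved:
            break

    pts = rotated_points()
    # re-anchor: laryngeal centroid to the cuff-opening angle
    if "laryngeal" in organs:
        lar = np.stack([pts[a]["laryngeal"] for a in animals]).mean(axis=0)
        anchor = CUFF_OPENING_DEG - np.degrees(np.arctan2(lar[1], lar[0]))
    else:
        anchor = 0.0
    final_rot = {a: (rot[a] + anchor) % 360.0 for a in animals}
    pts = {a: {o: _rotate_xy(base[a][o][None], final_rot[a])[0] for o in organs}
           for a in animals}

    centroids = {o: np.stack([pts[a][o] for a in animals]).mean(axis=0)
                 for o in organs}
    rows = []
    for a in animals:
        for o in organs:
            d = float(np.hypot(*(pts[a][o] - centroids[o])))
            rows.append(dict(animal=a, organ=o, distance_um=d))
    dist = pd.DataFrame(rows)
    rotated = {a: {o: CoMRecord(x_um=pts[a][o][0], y_um=pts[a][o][1],
                                organ=o, technique=com_sets[a][o].technique,
                                animal=a, level=com_sets[a][o].level)
                   for o in organs} for a in animals}
    return ClusterizationResult(
        rotations_deg=final_rot, centroids_um=centroids,
        member_distances_um=dist,
        mean_dispersion_um=float(dist.distance_um.mean()),
        rotated=rotated)


def dispersion(result: ClusterizationResult,
               estimator: str = "mean") -> dict[str, float]:
    """Per-cluster dispersion: mean (or RMS) member-to-centroid distance."""
    if estimator not in ("mean", "rms"):
        raise ValueError("estimator must be 'mean' or 'rms'")
    out = {}
    for organ, sub in result.member_distances_um.groupby("organ"):
        d = sub.distance_um.to_numpy()
        out[organ] = float(d.mean() if estimator == "mean"
                           else np.sqrt((d ** 2).mean()))
    return out


def one_sample_ttest(values: np.ndarray) -> tuple[float, float]:
    """One-sample t-test against zero mean (n-1 degrees of freedom)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.allclose(v, v[0]):
        raise ValueError("zero variance; t statistic undefined")
    res = stats.ttest_1samp(v, popmean=0.0)
    return float(res.statistic), float(res.pvalue)
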