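"""Parametric geometry of the outflow-graft (OG) anastomosis.

An anastomosis configuration is described by three surgical parameters:
the axial distance ``d`` from the anatomic ventriculo-arterial junction
(AVJ) to the centre of the graft attachment, the cardinal side of the
ascending aorta the graft attaches to, and the angle the graft axis makes
with that side's anatomical plane. The graft itself is a 14 mm tube.

Coordinate convention (right-handed patient coordinates): axial axis
``+z``, coronal plane ``x-z`` (normal ``+y``), sagittal plane ``y-z``
(normal ``+x``). A *coronal-sided* graft attaches on the anterior (+y)
aspect with its axis in the y-z plane, so the angle between the graft
axis and the coronal plane is exactly the configured angle; a
*sagittal-sided* graft mirrors this with ``+x`` and the sagittal plane.

The default aorta is an idealised Type-I "candy-cane": a straight
ascending segment, a semicircular arch, and a straight descending
segment, at constant lumen radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AnastomosisParams",
    "MeasuredAnastomosis",
    "AortaModel",
    "SurfaceMesh",
    "default_aorta",
    "enumerate_configurations",
    "build_geometry",
    "measure_parameters",
]

DISTANCE_RANGE = (40.0, 60.0)  # mm
CORONAL_ANGLE_RANGE = (35.0, 55.0)  # deg, 45 +/- 10
SAGITTAL_ANGLE_RANGE = (45.0, 55.0)  # deg

DEFAULT_DISTANCES = (45.0, 50.0, 55.0)
DEFAULT_CORONAL_ANGLES = (35.0, 45.0, 55.0)
DEFAULT_SAGITTAL_ANGLES = (45.0, 55.0)


@dataclass(frozen=True)
class AnastomosisParams:
    """One OG placement: distance (mm), cardinal side, angle (deg)."""

    d: float
    side: str  # "coronal" | "sagittal"
    angle: float
    og_diameter: float = 14.0

    def __post_init__(self) -> None:
        if self.side not in ("coronal", "sagittal"):
            raise ValueError(f"side must be 'coronal' or 'sagittal', got {self.side!r}")
        lo, hi = DISTANCE_RANGE
        if not lo <= self.d <= hi:
            raise ValueError(f"d={self.d} mm outside the valid range [{lo}, {hi}] mm")
        lo, hi = CORONAL_ANGLE_RANGE if self.side == "coronal" else SAGITTAL_ANGLE_RANGE
        if not lo <= self.angle <= hi:
            raise ValueError(
                f"{self.side} angle={self.angle} deg outside [{lo}, {hi}] deg"
            )
        if self.og_diameter <= 0:
            raise ValueError("og_diameter must be strictly positive")


@dataclass(frozen=True)
class MeasuredAnastomosis:
    """Parameters recovered from a mesh; side may be 'ambiguous'."""

    d: float
    side: str
    angle: float
    og_diameter: float


@dataclass
class AortaModel:
    """Idealised aorta: centerline points, per-point radii, landmarks."""

    centerline: np.ndarray  # (n, 3) mm, ordered AVJ -> descending end
    radius: np.ndarray  # (n,) mm
    branch_ostia: dict[str, np.ndarray] = field(default_factory=dict)
    axial_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radius = np.broadcast_to(
            np.asarray(self.radius, dtype=float), (self.centerline.shape[0],)
        ).copy()
        if np.any(self.radius <= 0):
            raise ValueError("all lumen radii must be strictly positive")
        self.axial_axis = np.asarray(self.axial_axis, dtype=float)
        self.axial_axis /= np.linalg.norm(self.axial_axis)

    @property
    def avj_point(self) -> np.ndarray:
        return self.centerline[0]


@dataclass
class SurfaceMesh:
    """Triangle surface mesh with per-vertex part labels.

    ``labels`` is 0 for aortic-tube vertices and 1 for OG vertices.
    ``frame`` carries the rigid landmarks needed to measure parameters:
    the AVJ reference point and the axial / coronal-normal /
    sagittal-normal directions. :meth:`transformed` moves vertices and
    landmarks together, so recovered parameters are rigid-motion
    invariant.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    labels: np.ndarray  # (n,) int
    frame: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.faces.size and self.faces.max() >= self.vertices.shape[0]:
            raise ValueError("face index out of range")
        if self.labels.shape[0] != self.vertices.shape[0]:
            raise ValueError("labels must be per-vertex")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Apply a rigid motion to vertices and frame landmarks."""
        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        frame = {}
        for key, val in self.frame.items():
            if key.endswith("_point"):
                frame[key] = rot @ val + tr
            else:
                frame[key] = rot @ val
        return SurfaceMesh(
            vertices=self.vertices @ rot.T + tr,
            faces=self.faces.copy(),
            labels=self.labels.copy(),
            frame=frame,
        )

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def export_stl(self, path) -> None:
        self.to_trimesh().export(path)


def default_aorta(
    ascending_length: float = 110.0,
    arch_radius: float = 40.0,
    descending_length: float = 150.0,
    lumen_radius: float = 15.0,
    n_points: int = 120,
) -> AortaModel:
    """Idealised Type-I candy-cane aorta (dimensions in mm).

    The AVJ sits at the origin; the ascending aorta runs along +z, the
    arch is a semicircle in the x-z plane, and the descending aorta runs
    back down parallel to -z.
    """
    l_arch = np.pi * arch_radius
    total = ascending_length + l_arch + descending_length
    s = np.linspace(0.0, total, n_points)
    pts = np.empty((n_points, 3))
    for i, si in enumerate(s):
        if si <= ascending_length:
            pts[i] = (0.0, 0.0, si)
        elif si <= ascending_length + l_arch:
            theta = (si - ascending_length) / arch_radius
            pts[i] = (
                -arch_radius * (1.0 - np.cos(theta)),
                0.0,
                ascending_length + arch_radius * np.sin(theta),
            )
        else:
            pts[i] = (
                -2.0 * arch_radius,
                0.0,
                ascending_length - (si - ascending_length - l_arch),
            )
    top = ascending_length + arch_radius
    ostia = {
        "Right Coronary Artery": np.array([lumen_radius, 0.0, 5.0]),
        "Left Coronary Artery": np.array([-lumen_radius, 0.0, 5.0]),
        "Right Subclavian Artery": np.array([-0.2 * arch_radius, 0.0, top]),
        "Right Common Carotid Artery": np.array([-0.5 * arch_radius, 0.0, top]),
        "Left Common Carotid Artery": np.array([-arch_radius, 0.0, top]),
        "Left Subclavian Artery": np.array([-1.5 * arch_radius, 0.0, top]),
        "Descending Aorta": pts[-1].copy(),
    }
    return AortaModel(centerline=pts, radius=np.full(n_points, lumen_radius),
                      branch_ostia=ostia)


def enumerate_configurations(
    distances=DEFAULT_DISTANCES,
    coronal_angles=DEFAULT_CORONAL_ANGLES,
    sagittal_angles=DEFAULT_SAGITTAL_ANGLES,
    og_diameter: float = 14.0,
) -> list[AnastomosisParams]:
    """Cartesian enumeration of anastomosis configurations.

    Order is deterministic: coronal before sagittal, then distance
    ascending, then angle ascending. The defaults give the 15-member
    study set (3 distances x 3 coronal angles + 3 distances x 2 sagittal
    angles).
    """
    if len(distances) == 0 or (len(coronal_angles) == 0 and len(sagittal_angles) == 0):
        raise ValueError("need at least one distance and one angle")
    out: list[AnastomosisParams] = []
    for side, angles in (("coronal", coronal_angles), ("sagittal", sagittal_angles)):
        for d in sorted(distances):
            for angle in sorted(angles):
                out.append(
                    AnastomosisParams(d=d, side=side, angle=angle, og_diameter=og_diameter)
                )
    return out


def _tube(path: np.ndarray, radius, resolution: int):
    """Sweep a circle along a polyline with parallel-transported frames."""
    path = np.asarray(path, dtype=float)
    n = path.shape[0]
    radius = np.broadcast_to(np.asarray(radius, dtype=float), (n,))
    tangents = np.gradient(path, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # initial normal: any vector not parallel to the first tangent
    ref = np.array([1.0, 0.0, 0.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    normal = ref - (ref @ tangents[0]) * tangents[0]
    normal /= np.linalg.norm(normal)
    theta = 2.0 * np.pi * np.arange(resolution) / resolution
    verts = np.empty((n, resolution, 3))
    for i in range(n):
        if i > 0:  # parallel transport of the frame
            normal = normal - (normal @ tangents[i]) * tangents[i]
            normal /= np.linalg.norm(normal)
        binormal = np.cross(tangents[i], normal)
        ring = (
            path[i]
            + radius[i] * np.outer(np.cos(theta), normal)
            + radius[i] * np.outer(np.sin(theta), binormal)
        )
        verts[i] = ring
    faces = []
    for i in range(n - 1):
        for j in range(resolution):
            a = i * resolution + j
            b = i * resolution + (j + 1) % resolution
            c = (i + 1) * resolution + j
            d = (i + 1) * resolution + (j + 1) % resolution
            faces.append((a, b, c))
            faces.append((b, d, c))
    return verts.reshape(-1, 3), np.array(faces, dtype=int)


def _side_vectors(side: str) -> tuple[np.ndarray, np.ndarray]:
    """(plane normal, in-plane downward direction) for a cardinal side."""
    if side == "coronal":
        return np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, -1.0])
    return np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, -1.0])


def build_geometry(
    aorta: AortaModel,
    params: AnastomosisParams,
    resolution: int = 32,
    og_length: float = 40.0,
) -> SurfaceMesh:
    """Emit the aorta tube plus the OG tube for one configuration.

    The OG attaches at axial distance ``d`` above the AVJ on the
    configured side; its axis leaves the aortic surface making the
    configured angle with the side's anatomical plane and tilting toward
    the pump (downward). The two tubes are emitted as labelled open
    surfaces (no boolean union).
    """
    avj = aorta.avj_point
    ax = aorta.axial_axis
    axial_pos = (aorta.centerline - avj) @ ax
    # the graft attaches to the ascending segment: the contiguous prefix of
    # the centerline whose tangent still runs along the axial axis
    tangents = np.gradient(aorta.centerline, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    along = tangents @ ax
    ascending = np.argmax(along < 0.99) or along.size
    max_d = axial_pos[:ascending].max()
    if params.d > max_d:
        raise ValueError(
            f"d={params.d} mm beyond the ascending-segment extent ({max_d:.1f} mm)"
        )
    idx = int(np.argmin(np.abs(axial_pos[:ascending] - params.d)))
    center = avj + params.d * ax
    r_lumen = float(aorta.radius[idx])

    normal, down = _side_vectors(params.side)
    alpha = np.radians(params.angle)
    v_out = np.sin(alpha) * normal + np.cos(alpha) * down
    p0 = center + r_lumen * normal  # anastomosis centre, on the aortic surface

    aorta_v, aorta_f = _tube(aorta.centerline, aorta.radius, resolution)
    og_path = p0 + np.linspace(0.0, og_length, 24)[:, None] * v_out
    og_v, og_f = _tube(og_path, params.og_diameter / 2.0, resolution)

    vertices = np.vstack([aorta_v, og_v])
    faces = np.vstack([aorta_f, og_f + aorta_v.shape[0]])
    labels = np.concatenate(
        [np.zeros(aorta_v.shape[0], dtype=int), np.ones(og_v.shape[0], dtype=int)]
    )
    frame = {
        "avj_point": avj.copy(),
        "axial_axis": ax.copy(),
        "coronal_normal": np.array([0.0, 1.0, 0.0]),
        "sagittal_normal": np.array([1.0, 0.0, 0.0]),
        "aorta_center_point": center,
    }
    return SurfaceMesh(vertices=vertices, faces=faces, labels=labels, frame=frame)


def _fit_cylinder(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares cylinder fit: returns (point on axis, axis, radius).

    Parametrised as spherical axis angles, an axis-point offset confined
    to the plane perpendicular to the initial axis (the along-axis
    component is unidentifiable), and the radius. Initialised from PCA:
    the tube is long relative to its radius, so the first principal
    direction is the axis.
    """
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis0 = vt[0]
    e1 = vt[1]
    e2 = vt[2]

    def residuals(x):
        axis = np.array([np.sin(x[0]) * np.cos(x[1]), np.sin(x[0]) * np.sin(x[1]),
                         np.cos(x[0])])
        offset = centered - (x[2] * e1 + x[3] * e2)
        radial = offset - np.outer(offset @ axis, axis)
        return np.linalg.norm(radial, axis=1) - x[4]

    theta0 = np.arccos(np.clip(axis0[2], -1, 1))
    phi0 = np.arctan2(axis0[1], axis0[0])
    radial0 = centered - np.outer(centered @ axis0, axis0)
    r0 = np.linalg.norm(radial0, axis=1).mean()
    sol = least_squares(residuals, x0=[theta0, phi0, 0.0, 0.0, r0], method="lm")
    th, ph = sol.x[0], sol.x[1]
    axis = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    return centroid + sol.x[2] * e1 + sol.x[3] * e2, axis, float(sol.x[4])


def measure_parameters(
    mesh: SurfaceMesh,
    aorta: AortaModel | None = None,
    ambiguity_tol_deg: float = 1.0,
) -> MeasuredAnastomosis:
    """Recover (d, side, angle, diameter) from a labelled anastomosis mesh.

    The OG axis and radius come from a least-squares cylinder fit to the
    OG-labelled vertices; the side is the anatomical plane whose normal
    the axis leans along most; the angle is between the axis and that
    plane; and ``d`` is the axial-plane distance between the AVJ
    reference and the attachment-end centre of the graft. If the axis
    leans equally toward both plane normals (within ``ambiguity_tol_deg``)
    the side is reported as ``"ambiguous"``.
    """
    og_mask = mesh.labels == 1
    if not og_mask.any():
        raise ValueError("mesh has no OG-labelled vertices; cannot measure")
    frame = mesh.frame
    if not {"avj_point", "axial_axis", "coronal_normal", "sagittal_normal"} <= set(frame):
        raise ValueError("mesh frame is missing the required landmarks")
    og_pts = mesh.vertices[og_mask]
    axis_pt, axis, radius = _fit_cylinder(og_pts)

    # attachment end = axis endpoint closer to the aorta vertex cloud
    proj = (og_pts - axis_pt) @ axis
    end_a = axis_pt + proj.min() * axis
    end_b = axis_pt + proj.max() * axis
    aorta_pts = mesh.vertices[~og_mask]
    ref = frame.get("aorta_center_point", aorta_pts.mean(axis=0))
    attach = end_a if np.linalg.norm(end_a - ref) < np.linalg.norm(end_b - ref) else end_b

    d = float(abs((attach - frame["avj_point"]) @ frame["axial_axis"]))

    lean_cor = abs(float(axis @ frame["coronal_normal"]))
    lean_sag = abs(float(axis @ frame["sagittal_normal"]))
    ang_cor = np.degrees(np.arcsin(np.clip(lean_cor, 0, 1)))
    ang_sag = np.degrees(np.arcsin(np.clip(lean_sag, 0, 1)))
    if abs(ang_cor - ang_sag) < ambiguity_tol_deg:
        side, angle = "ambiguous", float(max(ang_cor, ang_sag))
    elif ang_cor > ang_sag:
        side, angle = "coronal", float(ang_cor)
    else:
        side, angle = "sagittal", float(ang_sag)
    return MeasuredAnastomosis(d=d, side=side, angle=angle, og_diameter=2.0 * radius)
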