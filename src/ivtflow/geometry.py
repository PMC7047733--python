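"""Idealized intraventricular-tunnel (IVT) geometry.

After double-outlet-right-ventricle (DORV) correction the left ventricle
ejects through a surgically constructed tunnel running from the ventricular
septal defect (VSD) to the aortic valve orifice.  The idealized tunnel is
described by three geometric factors:

* ``d_sa`` — distance from the VSD centre to the aortic-valve plane (mm),
* ``a_lt`` — ejection angle of blood entering the tunnel, measured from the
  valve plane (degrees); ``a_lt = 0`` means the jet enters parallel to the
  valve plane and must turn a full 90 degrees,
* ``r_tt`` — turning radius of the tunnel centerline (mm).

The centerline is planar: an optional inlet straight, a circular arc of
radius ``r_tt`` spanning ``theta_bend = 90 - a_lt`` degrees that turns the
flow from the ejection direction to the valve-plane normal, and an outlet
straight that lands on the plane ``y = d_sa``.  A circular lumen swept along
the centerline gives the wall surface, exportable as STL/PLY.

Units are mm and degrees at the interface; radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

#: Default lumen bore, mm.  Chosen so that Re = rho*v*D/mu with blood
#: properties (1050 kg/m^3, 0.0035 Pa*s) and a 1 m/s systolic jet is ~4000,
#: the transitional regime the tunnel operates in.
DEFAULT_LUMEN_DIAMETER_MM = 13.33


class InfeasibleGeometryError(ValueError):
    """The tunnel cannot reach the aortic-valve plane (outlet run < 0)."""

    def __init__(self, deficit_mm: float):
        self.deficit_mm = float(deficit_mm)
        super().__init__(
            f"tunnel cannot reach the valve plane: outlet straight would be "
            f"{-self.deficit_mm:.4g} mm short (L_out < 0)"
        )


class SelfIntersectionError(ValueError):
    """Inner wall of the bend folds onto itself (r_tt < lumen radius)."""


@dataclass(frozen=True)
class TunnelParams:
    """One geometric configuration of the idealized tunnel.

    Parameters
    ----------
    d_sa : float
        VSD-to-aortic-valve-plane distance, mm. Must be positive.
    a_lt : float
        Ejection angle above the valve plane, degrees, in ``[0, 90)``.
    r_tt : float
        Turning radius of the centerline, mm, non-negative. ``r_tt = 0``
        degenerates to a sharp elbow.
    lumen_diameter : float
        Tunnel bore, mm.
    """

    d_sa: float
    a_lt: float
    r_tt: float
    lumen_diameter: float = DEFAULT_LUMEN_DIAMETER_MM

    def __post_init__(self) -> None:
        if not self.d_sa > 0:
            raise ValueError(f"d_sa must be > 0, got {self.d_sa}")
        if not (0 <= self.a_lt < 90):
            raise ValueError(f"a_lt must be in [0, 90) degrees, got {self.a_lt}")
        if self.r_tt < 0:
            raise ValueError(f"r_tt must be >= 0, got {self.r_tt}")
        if not self.lumen_diameter > 0:
            raise ValueError(
                f"lumen_diameter must be > 0, got {self.lumen_diameter}"
            )


@dataclass(frozen=True)
class Segment:
    """One centerline piece: a straight run or a circular arc."""

    kind: str  # "straight" | "arc"
    length: float  # mm, along the path
    start_direction_angle: float  # degrees from the valve plane (horizontal)
    turn_radius: float | None = None  # mm, arcs only


@dataclass(frozen=True)
class Centerline:
    """Planar tunnel centerline from the VSD centre to the valve plane.

    The path starts at the origin heading ``a_lt`` degrees above horizontal
    and ends on the plane ``y = d_sa`` heading along +y (the valve-plane
    normal).  ``vertices`` is a polyline sampling of the path in the x-y
    plane (z = 0), in mm.
    """

    segments: tuple[Segment, ...]
    l_in: float
    l_out: float
    bend_angle: float  # degrees
    total_length: float
    vertices: np.ndarray = field(repr=False)

    @property
    def start_point(self) -> np.ndarray:
        return self.vertices[0]

    @property
    def end_point(self) -> np.ndarray:
        return self.vertices[-1]


def _arc_points(
    start: np.ndarray, phi0: float, phi1: float, radius: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample an arc turning the heading from angle phi0 to phi1 (radians,
    counter-clockwise, phi1 > phi0).  Returns (points, end_direction)."""
    # Turning left: the arc centre sits at 90 deg left of the heading.
    centre = start + radius * np.array(
        [math.cos(phi0 + math.pi / 2), math.sin(phi0 + math.pi / 2), 0.0]
    )
    phis = np.linspace(phi0, phi1, n)
    # Position angle from centre to the point trails the heading by 90 deg.
    pts = centre + radius * np.stack(
        [np.cos(phis - math.pi / 2), np.sin(phis - math.pi / 2), np.zeros(n)],
        axis=1,
    )
    end_dir = np.array([math.cos(phi1), math.sin(phi1), 0.0])
    return pts, end_dir


def build_centerline(
    params: TunnelParams,
    l_in: float = 0.0,
    arc_step_deg: float = 1.0,
) -> Centerline:
    """Construct the planar centerline for one tunnel configuration.

    The outlet straight length follows from requiring the path to land on
    the valve plane::

        L_out = d_sa - L_in*sin(a_lt) - r_tt*cos(a_lt)

    Parameters
    ----------
    params : TunnelParams
        Geometric factors.
    l_in : float
        Inlet straight length, mm (default 0: the VSD opens directly into
        the bend).
    arc_step_deg : float
        Angular sampling of the arc polyline, degrees.

    Raises
    ------
    InfeasibleGeometryError
        If ``L_out < 0`` — the bend alone overshoots the valve plane.
    """
    if l_in < 0:
        raise ValueError(f"l_in must be >= 0, got {l_in}")
    a = math.radians(params.a_lt)
    theta_bend = 90.0 - params.a_lt
    theta_rad = math.radians(theta_bend)
    l_out = params.d_sa - l_in * math.sin(a) - params.r_tt * math.cos(a)
    if l_out < -1e-12:
        raise InfeasibleGeometryError(l_out)
    l_out = max(l_out, 0.0)
    arc_len = params.r_tt * theta_rad

    pts: list[np.ndarray] = [np.zeros(3)]
    direction = np.array([math.cos(a), math.sin(a), 0.0])
    segments: list[Segment] = []

    if l_in > 0:
        pts.append(pts[-1] + l_in * direction)
        segments.append(Segment("straight", l_in, params.a_lt))

    if params.r_tt > 0 and theta_bend > 0:
        n = max(2, int(math.ceil(theta_bend / arc_step_deg)) + 1)
        arc, direction = _arc_points(
            pts[-1], a, math.pi / 2, params.r_tt, n
        )
        pts.extend(arc[1:])
        segments.append(Segment("arc", arc_len, params.a_lt, params.r_tt))
    elif theta_bend > 0:
        # Sharp elbow: direction flips to vertical with no arc length.
        direction = np.array([0.0, 1.0, 0.0])

    if l_out > 0:
        pts.append(pts[-1] + l_out * direction)
        segments.append(Segment("straight", l_out, 90.0))

    vertices = np.asarray(pts)
    return Centerline(
        segments=tuple(segments),
        l_in=l_in,
        l_out=l_out,
        bend_angle=theta_bend,
        total_length=l_in + arc_len + l_out,
        vertices=vertices,
    )


def feasible(params: TunnelParams, l_in: float = 0.0) -> tuple[bool, str]:
    """Whether ``build_centerline`` succeeds, with a reason when it does not."""
    try:
        build_centerline(params, l_in=l_in)
    except InfeasibleGeometryError as err:
        return False, str(err)
    return True, "ok"


# ---------------------------------------------------------------------------
# Swept lumen surface


@dataclass(frozen=True)
class TunnelMesh:
    """Triangulated tunnel wall (optionally capped to a closed solid)."""

    vertices: np.ndarray  # (n, 3) mm
    triangles: np.ndarray  # (m, 3) int indices
    capped: bool

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @property
    def is_watertight(self) -> bool:
        return self.as_trimesh().is_watertight

    @property
    def volume(self) -> float:
        """Enclosed volume, mm^3 (meaningful only when capped)."""
        return float(self.as_trimesh().volume)


def _sample_centerline(
    centerline: Centerline, axial_step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample points and unit tangents at ~axial_step spacing, using the
    analytic segment parameterization (not finite differences)."""
    pts: list[np.ndarray] = []
    tans: list[np.ndarray] = []
    pos = np.zeros(3)
    for seg in centerline.segments:
        phi0 = math.radians(seg.start_direction_angle)
        if seg.kind == "straight":
            d = np.array([math.cos(phi0), math.sin(phi0), 0.0])
            n = max(1, int(math.ceil(seg.length / axial_step)))
            ts = np.linspace(0.0, seg.length, n + 1)
            for t in ts:
                pts.append(pos + t * d)
                tans.append(d)
            pos = pos + seg.length * d
        else:
            r = seg.turn_radius
            theta = seg.length / r
            n = max(2, int(math.ceil(seg.length / axial_step)))
            centre = pos + r * np.array(
                [math.cos(phi0 + math.pi / 2), math.sin(phi0 + math.pi / 2), 0.0]
            )
            for phi in np.linspace(phi0, phi0 + theta, n + 1):
                pts.append(
                    centre
                    + r
                    * np.array(
                        [math.cos(phi - math.pi / 2), math.sin(phi - math.pi / 2), 0.0]
                    )
                )
                tans.append(np.array([math.cos(phi), math.sin(phi), 0.0]))
            pos = pts[-1]
    # Merge duplicated junction samples.
    out_p: list[np.ndarray] = []
    out_t: list[np.ndarray] = []
    for p, t in zip(pts, tans):
        if out_p and np.linalg.norm(p - out_p[-1]) < 1e-12:
            out_t[-1] = t  # keep downstream tangent at a junction
            continue
        out_p.append(p)
        out_t.append(t)
    return np.asarray(out_p), np.asarray(out_t)


def build_surface_mesh(
    centerline: Centerline,
    diameter: float,
    n_circumferential: int = 64,
    axial_step: float = 0.5,
    capped: bool = True,
) -> TunnelMesh:
    """Sweep a circle of the given diameter along the centerline.

    Frames are rotation-minimizing; for this planar path the out-of-plane
    axis is a constant frame vector, so the frames are exact.  Vertex
    ordering is deterministic for bit-identical re-export.

    Raises
    ------
    SelfIntersectionError
        When the turn radius is smaller than the lumen radius on a bent
        path: the inner wall would fold through itself.
    ValueError
        On invalid resolution.
    """
    if n_circumferential < 8:
        raise ValueError(
            f"n_circumferential must be >= 8, got {n_circumferential}"
        )
    if not axial_step > 0:
        raise ValueError(f"axial_step must be > 0, got {axial_step}")
    if centerline.bend_angle > 0:
        min_radius = min(
            (s.turn_radius for s in centerline.segments if s.kind == "arc"),
            default=0.0,
        )
        if min_radius < diameter / 2:
            raise SelfIntersectionError(
                f"turn radius {min_radius:g} mm < lumen radius "
                f"{diameter / 2:g} mm: inner wall self-intersects"
            )

    pts, tans = _sample_centerline(centerline, axial_step)
    n_rings = len(pts)
    radius = diameter / 2.0
    binormal = np.array([0.0, 0.0, 1.0])  # plane normal, constant RMF axis
    phis = 2 * np.pi * np.arange(n_circumferential) / n_circumferential

    verts = np.empty((n_rings * n_circumferential, 3))
    for i, (p, t) in enumerate(zip(pts, tans)):
        normal = np.cross(binormal, t)  # in-plane, unit by construction
        ring = (
            p
            + radius * np.cos(phis)[:, None] * normal
            + radius * np.sin(phis)[:, None] * binormal
        )
        verts[i * n_circumferential : (i + 1) * n_circumferential] = ring

    faces: list[tuple[int, int, int]] = []
    C = n_circumferential
    for i in range(n_rings - 1):
        for j in range(C):
            a = i * C + j
            b = i * C + (j + 1) % C
            c = (i + 1) * C + j
            d = (i + 1) * C + (j + 1) % C
            faces.append((a, b, c))
            faces.append((b, d, c))

    if capped:
        start_centre = len(verts)
        verts = np.vstack([verts, pts[0], pts[-1]])
        end_centre = start_centre + 1
        for j in range(C):
            faces.append((start_centre, j, (j + 1) % C))
        base = (n_rings - 1) * C
        for j in range(C):
            faces.append((end_centre, base + (j + 1) % C, base + j))

    return TunnelMesh(
        vertices=verts, triangles=np.asarray(faces, dtype=np.int64), capped=capped
    )


_MESH_FORMATS = {"stl-binary": "stl", "stl-ascii": "stl_ascii", "ply": "ply"}


def write_mesh(mesh: TunnelMesh, path, fmt: str = "stl-binary") -> None:
    """Export a tunnel mesh to binary STL, ASCII STL, or PLY.

    Binary STL follows the standard layout: 80-byte header, uint32 triangle
    count, then little-endian 50-byte triangle records.
    """
    if fmt not in _MESH_FORMATS:
        raise ValueError(
            f"unknown format {fmt!r}; expected one of {sorted(_MESH_FORMATS)}"
        )
    if len(mesh.vertices) == 0 or len(mesh.triangles) == 0:
        raise ValueError("cannot write an empty mesh")
    tm = mesh.as_trimesh()
    tm.export(str(path), file_type=_MESH_FORMATS[fmt])
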