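"""Camera, ring and voxel-grid geometry.

World frame convention
----------------------
Right-handed Cartesian frame in mm.  The +y axis is vertical; camera
optical axes lie in the horizontal x--z plane, pointing at the world
origin.  The multi-angle acquisition rotates the *source* about +y,
which is implemented as rotating every camera by the negative angle.
A camera with the identity pose sits on the +z axis: its front-face
center is at ``(0, 0, ring_radius)``, its in-plane detector axes are
world x and world y, and its outward normal is +z.

Each hybrid camera is a pair of pixelated scintillator planes: a 45x45
front plane (1 mm pitch, 3 mm thick) with a central 3x3 mm^2 aperture
that doubles as a pinhole, and a 45x45 rear plane (1 mm pitch, 5 mm
thick) 40 mm behind it.  Pixel indexing is 0-based ``(ix, iy)`` with
pixel (22, 22) on the optical axis; pixel centers live on the entrance
face of each plane (no depth-of-interaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VERTICAL_AXIS = np.array([0.0, 1.0, 0.0])


def rot_y(angle_rad: float) -> np.ndarray:
    """Rotation matrix about the world vertical (+y) axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class DetectorPlane:
    role: str  # "front" | "rear"
    n_x: int = 45
    n_y: int = 45
    pixel_pitch: float = 1.0  # mm
    thickness: float = 3.0  # mm
    hole_half_width: float = 0.0  # mm, 0 for rear

    def __post_init__(self):
        if self.role not in ("front", "rear"):
            raise ValueError("role must be 'front' or 'rear'")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def half_extent(self) -> float:
        """Half width of the transverse footprint in mm."""
        return 0.5 * self.n_x * self.pixel_pitch


def default_front_plane() -> DetectorPlane:
    return DetectorPlane("front", thickness=3.0, hole_half_width=1.5)


def default_rear_plane() -> DetectorPlane:
    return DetectorPlane("rear", thickness=5.0, hole_half_width=0.0)


@dataclass(frozen=True)
class CameraGeometry:
    """Two-plane camera with a rigid pose.

    ``position`` is the front-face center in world mm; ``rotation`` maps
    detector-local axes to world axes (columns: in-plane x, in-plane y,
    outward normal pointing away from the imaged region).
    """

    front: DetectorPlane = field(default_factory=default_front_plane)
    rear: DetectorPlane = field(default_factory=default_rear_plane)
    plane_separation: float = 40.0  # mm, front face to rear face
    position: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 150.0]))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", r)

    # -- frame vectors -------------------------------------------------
    @property
    def e_x(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def e_y(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def axis_out(self) -> np.ndarray:
        """Unit outward normal (from imaged region toward the camera)."""
        return self.rotation[:, 2]

    def plane_origin(self, plane: str) -> np.ndarray:
        """World position of the entrance-face center of ``plane``."""
        if plane == "front":
            return self.position
        if plane == "rear":
            return self.position + self.plane_separation * self.axis_out
        raise ValueError("plane must be 'front' or 'rear'")

    def _plane_spec(self, plane: str) -> DetectorPlane:
        if plane == "front":
            return self.front
        if plane == "rear":
            return self.rear
        raise ValueError("plane must be 'front' or 'rear'")

    # -- operations ----------------------------------------------------
    def pixel_center_world(self, plane: str, ix, iy) -> np.ndarray:
        """World position (mm) of the center of pixel ``(ix, iy)``.

        Vectorized over ``ix``/``iy``; the center pixel of each 45x45
        plane lies on the optical axis.
        """
        spec = self._plane_spec(plane)
        ix = np.asarray(ix)
        iy = np.asarray(iy)
        if np.any(ix < 0) or np.any(ix >= spec.n_x) or np.any(iy < 0) or np.any(iy >= spec.n_y):
            raise IndexError("pixel index out of range")
        cx = (ix - (spec.n_x - 1) / 2.0) * spec.pixel_pitch
        cy = (iy - (spec.n_y - 1) / 2.0) * spec.pixel_pitch
        origin = self.plane_origin(plane)
        return (
            origin
            + np.multiply.outer(cx, self.e_x)
            + np.multiply.outer(cy, self.e_y)
        )

    def local_coords(self, plane: str, points: np.ndarray):
        """Project world ``points`` (..., 3) into in-plane coordinates."""
        rel = np.asarray(points, dtype=float) - self.plane_origin(plane)
        return rel @ self.e_x, rel @ self.e_y

    def ray_passes_hole(self, src, dst) -> bool:
        """True iff segment src->dst crosses the front aperture.

        The test is done at the front-face entrance plane only (no edge
        penetration modelling).
        """
        src = np.asarray(src, dtype=float)
        dst = np.asarray(dst, dtype=float)
        n = self.axis_out
        denom = (dst - src) @ n
        if abs(denom) < 1e-12:
            raise ValueError("segment is parallel to the front plane")
        t = ((self.position - src) @ n) / denom
        p = src + t * (dst - src)
        xi, eta = self.local_coords("front", p)
        h = self.front.hole_half_width
        return bool(max(abs(xi), abs(eta)) <= h)

    def rotated(self, angle_rad: float) -> "CameraGeometry":
        """Camera rigidly rotated about the world vertical axis."""
        r = rot_y(angle_rad)
        return replace(self, position=r @ self.position, rotation=r @ self.rotation)


def ring_cameras(n_cameras: int = 4, ring_diameter: float = 300.0) -> list[CameraGeometry]:
    """Evenly spaced cameras looking at the origin (front faces at R)."""
    base = CameraGeometry(position=np.array([0.0, 0.0, ring_diameter / 2.0]))
    return [base.rotated(2.0 * np.pi * c / n_cameras) for c in range(n_cameras)]


@dataclass(frozen=True)
class AcquisitionSetup:
    cameras: list[CameraGeometry]
    angles_deg: tuple[float, ...] = (0.0, 30.0, 60.0)
    ring_diameter: float = 300.0

    def __post_init__(self):
        a = tuple(float(x) for x in self.angles_deg)
        if len(a) == 0:
            raise ValueError("angle list must be non-empty")
        if any(not (0.0 <= x < 360.0) for x in a):
            raise ValueError("angles must lie in [0, 360) degrees")
        if any(a[i + 1] <= a[i] for i in range(len(a) - 1)):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles_deg", a)

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)


def default_ring(
    n_cameras: int = 4,
    ring_diameter: float = 300.0,
    angles_deg=(0.0, 30.0, 60.0),
) -> AcquisitionSetup:
    """The default acquisition: 4 cameras at 90 deg, opposite faces
    300 mm apart, 3 source rotations of 30 deg (12 effective angles)."""
    return AcquisitionSetup(
        cameras=ring_cameras(n_cameras, ring_diameter),
        angles_deg=tuple(angles_deg),
        ring_diameter=ring_diameter,
    )


def build_multi_angle(setup: AcquisitionSetup):
    """Expand an acquisition into per-angle camera poses.

    Rotating the source by +theta is equivalent to rotating every camera
    by -theta; ``angle_id`` enumerates the angle list.
    """
    if not setup.cameras:
        raise ValueError("setup has no cameras")
    out = []
    for angle_id, ang in enumerate(setup.angles_deg):
        rad = -np.deg2rad(ang)
        out.append((angle_id, [cam.rotated(rad) for cam in setup.cameras]))
    return out


@dataclass(frozen=True, eq=False)
class VoxelGrid:
    """Axis-aligned voxel grid with half-open voxel intervals.

    ``origin`` is the world position (mm) of the lower corner of voxel
    (0, 0, 0); a world point on a boundary belongs to the lower-index
    voxel.  The half width ``a = voxel_pitch / 2`` enters the Compton
    cone system matrix as the voxel size parameter.
    """

    origin: np.ndarray
    voxel_pitch: float
    shape: tuple[int, int, int]

    def __post_init__(self):
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid must contain at least one voxel")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    def __eq__(self, other):
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.voxel_pitch == other.voxel_pitch
            and np.array_equal(self.origin, other.origin)
        )

    def __hash__(self):
        return hash((self.shape, self.voxel_pitch, tuple(self.origin)))

    @classmethod
    def centered(cls, n: int | tuple[int, int, int], voxel_pitch: float = 2.3) -> "VoxelGrid":
        """Grid centered on the world origin (the default FOV)."""
        shape = (n, n, n) if np.isscalar(n) else tuple(n)
        origin = -0.5 * voxel_pitch * np.asarray(shape, dtype=float)
        return cls(origin=origin, voxel_pitch=voxel_pitch, shape=shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def half_voxel(self) -> float:
        return 0.5 * self.voxel_pitch

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_pitch

    def centers(self) -> np.ndarray:
        """(n_voxels, 3) world voxel centers, C-ordered (x fastest-varying
        last)."""
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def world_to_index(self, points) -> np.ndarray:
        """Voxel indices of world points.

        A point exactly on a voxel boundary belongs to the lower-index
        voxel (intervals are open below, closed above).
        """
        rel = (np.asarray(points, dtype=float) - self.origin) / self.voxel_pitch
        return (np.ceil(rel) - 1).astype(np.int64)

    def contains_index(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)

    def index_to_world(self, idx) -> np.ndarray:
        """World center of voxel ``idx`` (..., 3)."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_pitch
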