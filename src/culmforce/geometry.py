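"""Fibre geometry from label volumes and the cylindrical analysis grid.

Centerlines are recovered slice by slice (connected components reduced to
centroids, chained across slices by nearest-neighbour assignment), bundle
counts and inclines are summarized per ring, and the cylindrical voxel grid
that the mechanics stage runs on is built either from a parametric geometry
or from an extracted fibre set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .errors import DegenerateError, ParameterError, SpatialError
from .synthetic_data import (
    LABEL_INNER_BUNDLE,
    LABEL_OUTER_BUNDLE,
    RING_INNER,
    RING_OUTER,
    FibreCenterline,
    LabelVolume,
    StemGeometry,
    VolumeSpec,
)


@dataclass
class FibreSet:
    """Extracted or parametric centerlines with ring membership."""

    fibres: list[FibreCenterline]
    ring_labels: list[str]
    source_spec: VolumeSpec | None = None

    def __post_init__(self) -> None:
        if len(self.fibres) != len(self.ring_labels):
            raise ParameterError("fibres and ring_labels must be parallel lists")

    @property
    def n_fibres(self) -> int:
        return len(self.fibres)

    @classmethod
    def from_geometry(cls, geometry: StemGeometry) -> "FibreSet":
        return cls(list(geometry.fibres), list(geometry.ring_labels))


def compute_incline(fibre: FibreCenterline | np.ndarray) -> float:
    """Incline of a centerline versus the cross-sectional plane, degrees.

    Uses the mean finite-difference tangent: arctan of total rise over the
    summed per-step horizontal drift.  A fibre with zero drift is vertical
    (90 degrees).  Exact on straight fibres; on curved (helical) paths the
    chordal drift underestimates the arc by O(step^2), which vanishes with
    step refinement.
    """
    pts = fibre.points if isinstance(fibre, FibreCenterline) else np.asarray(fibre, float)
    if pts.shape[0] < 2:
        raise ParameterError("need at least 2 points to compute an incline")
    d = np.diff(pts, axis=0)
    if np.any(d[:, 2] <= 0):
        raise DegenerateError("duplicate or non-increasing z values in centerline")
    drift = float(np.hypot(d[:, 0], d[:, 1]).mean())
    rise = float(d[:, 2].mean())
    if drift == 0.0:
        return 90.0
    return float(np.degrees(np.arctan2(rise, drift)))


def extract_bundle_centerlines(volume: LabelVolume) -> FibreSet:
    """Reduce bundle labels to per-slice centroids and chain them into fibres.

    Centroids of each bundle label's connected components are linked across
    consecutive slices by minimum-cost assignment on horizontal distance
    (which handles azimuthal wraparound, coordinates being Cartesian).  A
    chain missing from more than one consecutive slice is split with a
    broken-fibre warning.  Chains spanning fewer than 2 slices are dropped.
    """
    nx, ny, nz = volume.spec.shape
    vx, vy, vz = volume.spec.voxel_size
    fx, fy, _ = volume.spec.field_of_view
    # max credible horizontal jump per slice: 3x the drift of a 45-degree fibre
    max_jump = 3.0 * vz

    fibres: list[FibreCenterline] = []
    rings: list[str] = []
    for code, ring in ((LABEL_OUTER_BUNDLE, RING_OUTER), (LABEL_INNER_BUNDLE, RING_INNER)):
        chains: list[dict] = []          # each: {"pts": [...], "misses": int, "open": bool}
        for iz in range(nz):
            mask = volume.data[iz] == code
            centroids = []
            if mask.any():
                lab = measure.label(mask, connectivity=2)
                for rp in measure.regionprops(lab):
                    cy, cx = rp.centroid
                    centroids.append(((cx + 0.5) * vx - fx / 2.0,
                                      (cy + 0.5) * vy - fy / 2.0))
            z = (iz + 0.5) * vz
            open_idx = [i for i, c in enumerate(chains) if c["open"]]
            assigned = set()
            if open_idx and centroids:
                cost = np.array([[np.hypot(chains[i]["pts"][-1][0] - x,
                                           chains[i]["pts"][-1][1] - y)
                                  for (x, y) in centroids] for i in open_idx])
                rows, cols = linear_sum_assignment(cost)
                for r, c in zip(rows, cols):
                    if cost[r, c] <= max_jump * (chains[open_idx[r]]["misses"] + 1):
                        ch = chains[open_idx[r]]
                        x, y = centroids[c]
                        ch["pts"].append((x, y, z))
                        ch["misses"] = 0
                        assigned.add(c)
            for i in open_idx:
                ch = chains[i]
                if ch["pts"][-1][2] < z - 1e-9:  # not matched this slice
                    ch["misses"] += 1
                    if ch["misses"] > 1:
                        ch["open"] = False
                        if len(ch["pts"]) >= 2:
                            warnings.warn(
                                f"broken fibre: {ring} chain ending at z="
                                f"{ch['pts'][-1][2]:.2f} mm has a gap > 1 slice; splitting",
                                stacklevel=2,
                            )
            for c, (x, y) in enumerate(centroids):
                if c not in assigned:
                    chains.append({"pts": [(x, y, z)], "misses": 0, "open": True})
        for ch in chains:
            if len(ch["pts"]) < 2:
                continue
            pts = np.asarray(ch["pts"], dtype=float)
            d = np.diff(pts, axis=0).mean(axis=0)
            phi = float(np.degrees(np.arctan2(d[1], d[0]))) % 360.0
            fibres.append(FibreCenterline(pts, phi, compute_incline(pts)))
            rings.append(ring)
    return FibreSet(fibres, rings, volume.spec)


def count_bundles(fibres: FibreSet, outer_radius: float | None = None,
                  inner_radius: float | None = None) -> dict:
    """Per-ring bundle counts, optionally normalized per wall annulus area."""
    counts = {
        RING_OUTER: sum(r == RING_OUTER for r in fibres.ring_labels),
        RING_INNER: sum(r == RING_INNER for r in fibres.ring_labels),
    }
    out = {"outer": counts[RING_OUTER], "inner": counts[RING_INNER]}
    if outer_radius is not None and inner_radius is not None:
        area = np.pi * (outer_radius ** 2 - inner_radius ** 2)
        out["wall_area_mm2"] = float(area)
        out["outer_per_mm2"] = counts[RING_OUTER] / area
        out["inner_per_mm2"] = counts[RING_INNER] / area
    return out


def incline_summary(fibres: FibreSet) -> dict:
    """Per-fibre inclines plus per-ring mean and sd (degrees)."""
    per_fibre = np.array([compute_incline(f) for f in fibres.fibres])
    out = {"per_fibre_deg": per_fibre}
    for ring in (RING_OUTER, RING_INNER):
        vals = per_fibre[[i for i, r in enumerate(fibres.ring_labels) if r == ring]]
        out[ring] = {
            "mean_deg": float(vals.mean()) if vals.size else float("nan"),
            "sd_deg": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n": int(vals.size),
        }
    return out


# ---------------------------------------------------------------------------
# cylindrical analysis grid
# ---------------------------------------------------------------------------

@dataclass
class CylindricalGrid:
    """Cylindrical voxel lattice over the culm wall of a stem segment.

    Voxels are indexed (i_alpha, i_r, i_z) with half-open angular bins
    [alpha, alpha + d_alpha), radial increments dr = (Ro - Ri)/n_r between
    the wall radii and dz-thick cross-sections.  Fibre-associated voxels
    carry the local fibre tangent as their major axis.
    """

    alpha_step_deg: float
    n_r: int
    dz: float
    segment: float
    outer_radius: float
    inner_radius: float
    bundle_radius: float
    fibre_mask: np.ndarray = field(repr=False)        # (n_alpha, n_r, n_z) bool
    fibre_index: np.ndarray = field(repr=False)       # (n_alpha, n_r, n_z) int, -1 = none
    fibre_tangent: np.ndarray = field(repr=False)     # (n_alpha, n_r, n_z, 3)

    @property
    def n_alpha(self) -> int:
        return int(round(360.0 / self.alpha_step_deg))

    @property
    def n_z(self) -> int:
        return int(round(self.segment / self.dz))

    @property
    def dr(self) -> float:
        return (self.outer_radius - self.inner_radius) / self.n_r

    @property
    def voxel_count(self) -> int:
        return self.n_alpha * self.n_r * self.n_z

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_alpha, self.n_r, self.n_z)

    def alpha_centers_deg(self) -> np.ndarray:
        return (np.arange(self.n_alpha) + 0.5) * self.alpha_step_deg

    def r_centers(self) -> np.ndarray:
        return self.inner_radius + (np.arange(self.n_r) + 0.5) * self.dr

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.n_z) + 0.5) * self.dz

    def radial_hat(self) -> np.ndarray:
        a = np.deg2rad(self.alpha_centers_deg())
        return np.stack([np.cos(a), np.sin(a), np.zeros_like(a)], axis=-1)

    def tangential_hat(self) -> np.ndarray:
        a = np.deg2rad(self.alpha_centers_deg())
        return np.stack([-np.sin(a), np.cos(a), np.zeros_like(a)], axis=-1)

    def axes_at(self, i_alpha: int, i_r: int, i_z: int) -> np.ndarray:
        """Orthonormal major-axis triad (rows) of one voxel.

        Matrix voxels use (radial, tangential, axial); fibre voxels use the
        fibre tangent completed to an orthonormal basis.
        """
        if self.fibre_mask[i_alpha, i_r, i_z]:
            t = self.fibre_tangent[i_alpha, i_r, i_z]
            helper = np.array([0.0, 0.0, 1.0])
            if abs(t @ helper) > 0.999999:
                helper = np.array([1.0, 0.0, 0.0])
            u = np.cross(helper, t)
            u /= np.linalg.norm(u)
            return np.stack([t, u, np.cross(t, u)])
        r_hat = self.radial_hat()[i_alpha]
        a_hat = self.tangential_hat()[i_alpha]
        return np.stack([r_hat, a_hat, np.array([0.0, 0.0, 1.0])])

    def projected_windward_area(self, attack_azimuth_deg: float) -> np.ndarray:
        """Projected area (mm^2) of each outer-surface angular bin.

        The incoming force travels along azimuth ``attack_azimuth_deg`` -
        180 degrees; a surface strip [a1, a2] facing the flow projects area
        Ro * dz * (sin th2 - sin th1) onto the plane normal to the travel
        direction, where th is measured from the windward-most azimuth.
        Leeward bins have zero area; the windward sum is exactly 2 Ro dz
        per slice.
        """
        gamma = np.deg2rad(attack_azimuth_deg - 180.0)  # direction of travel
        edges = np.deg2rad(np.arange(self.n_alpha + 1) * self.alpha_step_deg)
        # windward azimuths face the incoming flow: cos(alpha - gamma) < 0,
        # i.e. alpha in (gamma + pi/2, gamma + 3 pi/2); clip bins to that arc
        lo = (edges[:-1] - gamma - np.pi / 2) % (2 * np.pi)
        hi = lo + np.deg2rad(self.alpha_step_deg)
        lo_c = np.clip(lo, 0.0, np.pi)
        hi_c = np.clip(hi, 0.0, np.pi)
        # theta measured from gamma + pi/2; |cos(alpha-gamma)| = sin(theta)
        area = np.cos(lo_c) - np.cos(hi_c)
        # bins straddling theta = 2 pi re-enter the windward arc at theta = 0
        wrap = hi > 2 * np.pi
        area[wrap] += 1.0 - np.cos(np.clip(hi[wrap] - 2 * np.pi, 0.0, np.pi))
        return np.maximum(self.outer_radius * self.dz * area, 0.0)


def build_cylindrical_grid(geometry: StemGeometry | None = None,
                           fibres: FibreSet | None = None,
                           outer_radius: float | None = None,
                           inner_radius: float | None = None,
                           bundle_radius: float | None = None,
                           alpha_step_deg: float = 1.0,
                           n_r: int = 20,
                           dz: float = 1.0,
                           segment: float = 15.0,
                           length: float | None = None) -> CylindricalGrid:
    """Build the cylindrical analysis grid and associate voxels with fibres.

    With the defaults (1-degree azimuthal steps, 20 radial increments,
    1 mm cross-sections, 15 mm segment) the grid has 360 * 20 * 15 =
    108000 voxels.  A voxel is fibre-associated when its centre lies within
    ``bundle_radius`` of a centerline; such voxels take the local fibre
    tangent as major axis.
    """
    if geometry is not None:
        p = geometry.params
        outer_radius = p.outer_radius
        inner_radius = p.inner_radius
        bundle_radius = p.bundle_radius
        length = p.length
        fibre_list = geometry.fibres
    elif fibres is not None:
        if outer_radius is None or inner_radius is None or bundle_radius is None:
            raise ParameterError("radii and bundle_radius required with a bare FibreSet")
        fibre_list = fibres.fibres
        if length is None:
            length = max((f.points[:, 2].max() for f in fibre_list), default=segment)
    else:
        raise ParameterError("either geometry or fibres must be given")

    if alpha_step_deg <= 0 or abs(360.0 / alpha_step_deg - round(360.0 / alpha_step_deg)) > 1e-9:
        raise ParameterError(f"alpha_step_deg={alpha_step_deg} must divide 360")
    if dz <= 0 or abs(segment / dz - round(segment / dz)) > 1e-9:
        raise ParameterError(f"dz={dz} must divide the segment length {segment}")
    if n_r <= 0:
        raise ParameterError("n_r must be positive")
    if length is not None and segment > length + 1e-9:
        raise SpatialError(f"segment {segment} mm exceeds stem length {length} mm")

    n_alpha = int(round(360.0 / alpha_step_deg))
    n_z = int(round(segment / dz))
    alpha = np.deg2rad((np.arange(n_alpha) + 0.5) * alpha_step_deg)
    r = inner_radius + (np.arange(n_r) + 0.5) * (outer_radius - inner_radius) / n_r
    zc = (np.arange(n_z) + 0.5) * dz
    cx = np.cos(alpha)[:, None] * r[None, :]          # (n_alpha, n_r)
    cy = np.sin(alpha)[:, None] * r[None, :]

    fibre_mask = np.zeros((n_alpha, n_r, n_z), dtype=bool)
    fibre_index = np.full((n_alpha, n_r, n_z), -1, dtype=int)
    fibre_tangent = np.zeros((n_alpha, n_r, n_z, 3))
    best = np.full((n_alpha, n_r, n_z), np.inf)
    for k, f in enumerate(fibre_list):
        zs = f.points[:, 2]
        in_span = (zc >= zs.min() - 1e-9) & (zc <= zs.max() + 1e-9)
        if not in_span.any():
            continue
        xy = f.xy_at(zc)                              # (n_z, 2)
        tans = _local_tangents(f, zc)                 # (n_z, 3)
        for iz in np.nonzero(in_span)[0]:
            d = np.hypot(cx - xy[iz, 0], cy - xy[iz, 1])
            hit = (d <= bundle_radius) & (d < best[:, :, iz])
            if hit.any():
                best[:, :, iz][hit] = d[hit]
                fibre_mask[:, :, iz][hit] = True
                fibre_index[:, :, iz][hit] = k
                fibre_tangent[:, :, iz][hit] = tans[iz]

    return CylindricalGrid(alpha_step_deg, n_r, dz, segment,
                           outer_radius, inner_radius,
                           bundle_radius if bundle_radius is not None else 0.0,
                           fibre_mask, fibre_index, fibre_tangent)


def _local_tangents(fibre: FibreCenterline, z: np.ndarray) -> np.ndarray:
    """Unit tangents of a centerline interpolated at heights ``z`` (up-pointing)."""
    pts = fibre.points
    if pts.shape[0] < 2:
        raise ParameterError("fibre needs at least 2 points for tangents")
    g = np.gradient(pts, axis=0)
    t = np.column_stack([np.interp(z, pts[:, 2], g[:, i]) for i in range(3)])
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    t = t / norm
    t[t[:, 2] < 0] *= -1.0
    return t
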