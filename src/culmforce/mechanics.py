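"""Force-redistribution model on the cylindrical stem grid.

A horizontal surface pressure loads the windward outer voxels; force is
passed radially inward column by column with magnitude conservation
(|Fin| = |Fout| at every voxel).  Matrix voxels carry no axial component
under a horizontal load; voxels associated with vascular fibres deflect
the tangent-aligned part of the force out of the attack plane, which is
accumulated into a warp field.  Per-fibre axial/bending partitioning of a
unit impact and its 360-degree attack sweep are closed-form projections of
the impact vector onto each fibre's mean tangent.  No elastic constitutive
law is involved: the model is pure force bookkeeping on the grid axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateError, GeometryError, ParameterError
from .geometry import CylindricalGrid, FibreSet
from .synthetic_data import FibreCenterline


@dataclass
class ImpactCondition:
    """A horizontal attack: azimuth in degrees (1-360), surface pressure in
    N/m^2 and the per-fibre unit impact force in N."""

    attack_azimuth_deg: float = 90.0
    pressure: float = 1.0            # N/m^2
    fibre_impact_force: float = 1.0  # N

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ParameterError("pressure must be positive")
        if self.fibre_impact_force <= 0:
            raise ParameterError("fibre impact force must be positive")
        a = self.attack_azimuth_deg
        if not (0.0 < a <= 360.0):
            wrapped = a % 360.0 or 360.0
            warnings.warn(
                f"attack azimuth {a} outside (0, 360]; wrapped to {wrapped}",
                stacklevel=2,
            )
            self.attack_azimuth_deg = wrapped

    @property
    def direction(self) -> np.ndarray:
        """Unit travel direction of the impacting force (toward the axis)."""
        g = np.deg2rad(self.attack_azimuth_deg - 180.0)
        return np.array([np.cos(g), np.sin(g), 0.0])


@dataclass
class ForceField:
    """Per-voxel incoming/outgoing force vectors on the cylindrical grid."""

    f_in: np.ndarray                 # (n_alpha, n_r, n_z, 3) N
    f_out: np.ndarray                # same shape
    impact: ImpactCondition
    conservation_residual: float = 0.0

    @property
    def pressure_magnitude(self) -> np.ndarray:
        """|Fin| per voxel, the scalar rendered in cross-section maps."""
        return np.linalg.norm(self.f_in, axis=-1)


@dataclass
class WarpField:
    """Out-of-plane (fibre-deflected) force per (alpha, r) cell, N.

    Signed sums of the tangent-aligned force components removed from the
    in-plane propagation at fibre voxels, accumulated over the segment
    height.  Identically zero for a fibre-free stem.
    """

    values: np.ndarray               # (n_alpha, n_r)
    grid: CylindricalGrid = field(repr=False)

    def to_cartesian(self, n: int = 200) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Resample onto a Cartesian (x, y) lattice for rendering.

        Returns (x, y, warp) with NaN outside the wall annulus.
        """
        g = self.grid
        lim = g.outer_radius
        x = np.linspace(-lim, lim, n)
        y = np.linspace(-lim, lim, n)
        gx, gy = np.meshgrid(x, y)
        rr = np.hypot(gx, gy)
        aa = np.degrees(np.arctan2(gy, gx)) % 360.0
        ia = np.clip((aa / g.alpha_step_deg).astype(int), 0, g.n_alpha - 1)
        ir = np.clip(((rr - g.inner_radius) / g.dr).astype(int), 0, g.n_r - 1)
        out = self.values[ia, ir]
        out = np.where((rr >= g.inner_radius) & (rr <= g.outer_radius), out, np.nan)
        return gx, gy, out


@dataclass
class FibreForce:
    """Axial/bending split of a unit impact on one fibre.

    ``axial`` is signed: positive = stretching (component along the
    up-pointing tangent), negative = compression.  ``bending`` is the
    nonnegative remainder; axial^2 + bending^2 = impact^2.
    """

    axial: float      # F_N, N
    bending: float    # F_b, N


@dataclass
class AttackSweepProfile:
    """Mean per-fibre force fractions for attack angles 1..360 degrees."""

    alphas_deg: np.ndarray           # (360,)
    mean_fb_over_fi: np.ndarray      # unsigned bending fraction
    mean_fn_over_fi: np.ndarray      # signed axial fraction

    @property
    def bending_amplitude(self) -> float:
        return float(self.mean_fb_over_fi.max() - self.mean_fb_over_fi.min())

    @property
    def axial_amplitude(self) -> float:
        return float(self.mean_fn_over_fi.max() - self.mean_fn_over_fi.min())


# ---------------------------------------------------------------------------
# grid loading and propagation
# ---------------------------------------------------------------------------

def surface_load(grid: CylindricalGrid, impact: ImpactCondition) -> ForceField:
    """Load windward outer-surface voxels with pressure x projected area.

    Forces point along the horizontal travel direction (attack azimuth -
    180 degrees).  Areas are in mm^2, pressure in N/m^2, so forces carry a
    1e-6 conversion.  All other voxels are zero.
    """
    f_in = np.zeros(grid.shape + (3,))
    area_mm2 = grid.projected_windward_area(impact.attack_azimuth_deg)   # (n_alpha,)
    mag = impact.pressure * area_mm2 * 1e-6                              # N
    d = impact.direction
    f_in[:, -1, :, :] = mag[:, None, None] * d[None, None, :]
    return ForceField(f_in, f_in.copy(), impact)


def propagate_forces(field: ForceField, grid: CylindricalGrid) -> tuple[ForceField, WarpField]:
    """Pass the surface load voxel-to-voxel radially inward.

    In each (alpha, z) column the running force enters a voxel as Fin and
    leaves re-expressed on the voxel's major axes with |Fout| = |Fin|.  At
    matrix voxels the outgoing force is purely radial (zero axial part for
    a horizontal load).  At fibre voxels the component along the fibre
    tangent is retained out of plane and accumulated into the warp field;
    the remaining magnitude continues inward.  Propagation stops at the
    inner wall.  Magnitudes are accounted quadratically (the split is an
    orthogonal decomposition), and the residual

        |sqrt(m_wall^2 + sum a^2) - m_surface| / m_surface

    summed over columns is stored on the returned field.
    """
    n_alpha, n_r, n_z = grid.shape
    f_in = np.zeros(grid.shape + (3,))
    f_out = np.zeros(grid.shape + (3,))
    warp = np.zeros((n_alpha, n_r))
    r_in = -grid.radial_hat()                        # inward radial, (n_alpha, 3)

    running = field.f_in[:, -1, :, :].copy()         # (n_alpha, n_z, 3)
    m0_sq = np.einsum("azk,azk->az", running, running)
    deflected_sq = np.zeros((n_alpha, n_z))
    for ir in range(n_r - 1, -1, -1):
        f_in[:, ir, :, :] = running
        mag = np.linalg.norm(running, axis=-1)       # (n_alpha, n_z)
        mask = grid.fibre_mask[:, ir, :]             # (n_alpha, n_z)
        out = mag[..., None] * r_in[:, None, :]      # matrix rule: purely radial
        if mask.any():
            t = grid.fibre_tangent[:, ir, :, :]      # (n_alpha, n_z, 3)
            a = np.einsum("azk,azk->az", running, t)
            a = np.where(mask, a, 0.0)
            warp[:, ir] += a.sum(axis=1)
            deflected_sq += a * a
            # exact orthogonal split: tangent part + its complement, so
            # |Fout| = |Fin| to machine precision
            v_perp = running - a[..., None] * t
            rem = np.linalg.norm(v_perp, axis=-1)
            out = np.where(mask[..., None], a[..., None] * t + v_perp, out)
            running = np.where(mask[..., None], rem[..., None] * r_in[:, None, :],
                               mag[..., None] * r_in[:, None, :])
        else:
            running = out.copy()
        f_out[:, ir, :, :] = out

    m_wall_sq = np.einsum("azk,azk->az", running, running)
    loaded = m0_sq > 0
    residual = 0.0
    if loaded.any():
        acc = np.sqrt(m_wall_sq[loaded] + deflected_sq[loaded])
        residual = float(np.max(np.abs(acc - np.sqrt(m0_sq[loaded])) / np.sqrt(m0_sq[loaded])))
    if residual > 1e-9:
        raise GeometryError(f"force conservation violated: residual {residual:.3e}")
    out_field = ForceField(f_in, f_out, field.impact, conservation_residual=residual)
    return out_field, WarpField(warp, grid)


# ---------------------------------------------------------------------------
# per-fibre partitioning and the attack sweep
# ---------------------------------------------------------------------------

def _mean_tangent(fibre: FibreCenterline) -> np.ndarray:
    d = np.deg2rad(fibre.incline_deg)
    p = np.deg2rad(fibre.tilt_azimuth_deg)
    t = np.array([np.cos(d) * np.cos(p), np.cos(d) * np.sin(p), np.sin(d)])
    n = np.linalg.norm(t)
    if n == 0:
        raise DegenerateError("zero-length fibre tangent")
    t /= n
    return t if t[2] >= 0 else -t


def fibre_force_partition(fibre: FibreCenterline, impact: ImpactCondition) -> FibreForce:
    """Split a unit horizontal impact into axial and bending parts.

    With tangent t = (cos d cos p, cos d sin p, sin d) and horizontal
    impact vector F of magnitude F_I along the travel direction:
    F_N = F . t (signed, + stretching), F_b = sqrt(F_I^2 - F_N^2).
    """
    t = _mean_tangent(fibre)
    f_vec = impact.fibre_impact_force * impact.direction
    f_n = float(f_vec @ t)
    f_b = float(np.sqrt(max(impact.fibre_impact_force ** 2 - f_n ** 2, 0.0)))
    return FibreForce(axial=f_n, bending=f_b)


def sweep_attack_angles(fibres: FibreSet, impact: ImpactCondition | None = None) -> AttackSweepProfile:
    """Mean fibre force fractions over attack angles alpha = 1..360 degrees.

    Uses each fibre's mean tangent (exact for constant-incline helices);
    variation over stem height is not considered.
    """
    if fibres.n_fibres == 0:
        raise ParameterError("attack sweep needs at least one fibre")
    impact = impact or ImpactCondition()
    f_i = impact.fibre_impact_force
    tangents = np.array([_mean_tangent(f) for f in fibres.fibres])   # (nf, 3)
    alphas = np.arange(1, 361, dtype=float)
    g = np.deg2rad(alphas - 180.0)
    dirs = np.stack([np.cos(g), np.sin(g), np.zeros_like(g)], axis=-1)  # (360, 3)
    f_n = f_i * dirs @ tangents.T                                    # (360, nf)
    f_b = np.sqrt(np.maximum(f_i ** 2 - f_n ** 2, 0.0))
    return AttackSweepProfile(alphas, f_b.mean(axis=1) / f_i, f_n.mean(axis=1) / f_i)


def find_optimal_attack(profile: AttackSweepProfile, criterion: str = "bending") -> float:
    """Attack angle maximizing the selected mean force fraction.

    ``criterion='bending'`` (default) returns the argmax of the mean
    bending fraction; ``'axial'`` the argmax of |mean axial fraction|.
    Ties resolve to the smallest angle.
    """
    if criterion == "bending":
        curve = profile.mean_fb_over_fi
    elif criterion == "axial":
        curve = np.abs(profile.mean_fn_over_fi)
    else:
        raise ParameterError(f"unknown criterion {criterion!r}; use 'bending' or 'axial'")
    best = np.max(curve)
    idx = int(np.flatnonzero(curve >= best - 1e-12)[0])
    return float(profile.alphas_deg[idx])


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_fields(field: ForceField, warp: WarpField, out_dir,
                  grid: CylindricalGrid | None = None, slice_index: int | None = None) -> dict:
    """Write a pressure cross-section heatmap and a warped-plane plot.

    Pressure magnitude is colour-coded blue (minimal) to red (maximal) on
    a Cartesian back-transformation of one cross-section; the warp field
    is rendered as a surface-style deflection map.  Returns output paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    grid = grid or warp.grid
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"cannot write to {out_dir}: {exc}") from exc

    n_z = grid.n_z
    iz = n_z // 2 if slice_index is None else slice_index
    mag = field.pressure_magnitude[:, :, iz]          # (n_alpha, n_r)
    press = WarpField(mag, grid)                      # reuse the resampler
    gx, gy, img = press.to_cartesian()
    fig, ax = plt.subplots(figsize=(5, 4.2))
    pc = ax.pcolormesh(gx, gy, img, cmap="jet", shading="auto")
    fig.colorbar(pc, ax=ax, label="|F_in| (N)")
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"pressure magnitude, slice {iz}")
    pressure_png = out_dir / "pressure_cross_section.png"
    fig.savefig(pressure_png, dpi=120)
    plt.close(fig)

    gx, gy, wimg = warp.to_cartesian()
    fig = plt.figure(figsize=(5.5, 4.5))
    ax3 = fig.add_subplot(projection="3d")
    ax3.plot_surface(gx, gy, np.nan_to_num(wimg), cmap="coolwarm",
                     linewidth=0, antialiased=False)
    ax3.set_xlabel("x (mm)")
    ax3.set_ylabel("y (mm)")
    ax3.set_zlabel("out-of-plane force (N)")
    warp_png = out_dir / "warp_surface.png"
    fig.savefig(warp_png, dpi=120)
    plt.close(fig)

    return {"pressure": str(pressure_png), "warp": str(warp_png)}
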