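"""Synthetic inputs for the culm-analysis pipeline.

Everything downstream (centerline extraction, the force-redistribution
model, spectral decomposition, trait statistics) is exercised on data made
here: parametric hollow culms with two helical vascular-bundle rings,
rasterized label volumes emulating segmented MRI stacks, two-parent + F2
trait tables with additive inheritance, and noisy linear-mixture IR
spectra.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import GeometryError, LibraryError, ParameterError, SpatialError

#: label codes used in every synthetic volume
LABEL_BACKGROUND = 0
LABEL_MATRIX = 1
LABEL_INNER_BUNDLE = 2
LABEL_OUTER_BUNDLE = 3

RING_INNER = "inner"
RING_OUTER = "outer"


# ---------------------------------------------------------------------------
# stem geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StemParams:
    """Parametric description of a hollow culm with two bundle rings.

    Lengths are millimetres.  ``incline_mean_deg`` is the angle between the
    fibre tangent and the cross-sectional plane: 90 means parallel to the
    stem axis.  Use :func:`incline_from_axis_deg` to convert to the
    from-axis convention.
    """

    outer_radius: float
    inner_radius: float
    length: float
    n_outer_bundles: int
    n_inner_bundles: int
    ring_radius_outer: float
    ring_radius_inner: float
    bundle_radius: float
    incline_mean_deg: float = 90.0
    incline_sd_deg: float = 0.0
    azimuth_jitter_deg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.inner_radius < self.outer_radius):
            raise ParameterError(
                f"need 0 < Ri < Ro, got Ri={self.inner_radius}, Ro={self.outer_radius}"
            )
        if self.length <= 0:
            raise ParameterError("stem length must be positive")
        for name, r in (("ring_radius_outer", self.ring_radius_outer),
                        ("ring_radius_inner", self.ring_radius_inner)):
            if not (0.0 < r < self.outer_radius):
                raise ParameterError(f"{name}={r} outside (0, Ro)")
        if self.bundle_radius <= 0:
            raise ParameterError("bundle_radius must be positive")
        if not (0.0 < self.incline_mean_deg <= 90.0):
            raise ParameterError("incline_mean_deg must be in (0, 90]")
        if self.incline_sd_deg < 0 or self.azimuth_jitter_deg < 0:
            raise ParameterError("spread parameters must be nonnegative")
        if self.n_outer_bundles < 0 or self.n_inner_bundles < 0:
            raise ParameterError("bundle counts must be nonnegative")


def incline_from_axis_deg(incline_deg: float | np.ndarray) -> float | np.ndarray:
    """Convert plane-referenced incline (90 = vertical) to the from-axis angle."""
    return 90.0 - np.asarray(incline_deg) if np.ndim(incline_deg) else 90.0 - incline_deg


@dataclass
class FibreCenterline:
    """Ordered 3D points (mm) of one bundle centerline, one per z-step."""

    points: np.ndarray            # (n, 3) columns x, y, z
    tilt_azimuth_deg: float       # direction of horizontal drift (phi)
    incline_deg: float            # delta, from the cross-sectional plane

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError("centerline points must be an (n, 3) array")
        if self.points.shape[0] >= 2 and not np.all(np.diff(self.points[:, 2]) > 0):
            raise ParameterError("centerline z must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def xy_at(self, z: float | np.ndarray) -> np.ndarray:
        """Interpolate the horizontal position at height ``z`` (mm)."""
        zs = self.points[:, 2]
        x = np.interp(z, zs, self.points[:, 0])
        y = np.interp(z, zs, self.points[:, 1])
        return np.stack([x, y], axis=-1)

    def mean_tangent(self) -> np.ndarray:
        """Unit mean finite-difference tangent, canonicalized to point up."""
        d = np.diff(self.points, axis=0).mean(axis=0)
        n = np.linalg.norm(d)
        if n == 0:
            raise GeometryError("degenerate fibre: zero-length tangent")
        t = d / n
        return t if t[2] >= 0 else -t


@dataclass
class StemGeometry:
    params: StemParams
    fibres: list[FibreCenterline]
    ring_labels: list[str]        # RING_OUTER / RING_INNER, parallel to fibres

    def __post_init__(self) -> None:
        if len(self.fibres) != len(self.ring_labels):
            raise ParameterError("fibres and ring_labels must be parallel lists")

    @property
    def n_fibres(self) -> int:
        return len(self.fibres)


def generate_stem_geometry(params: StemParams, z_step: float = 0.5) -> StemGeometry:
    """Place helical bundle centerlines on the two rings of a culm.

    Fibres sit at equal azimuthal spacing per ring plus Gaussian jitter.
    Each centerline is a circular-helix segment of constant ring radius
    whose tangent makes the ring's incline angle with the cross-sectional
    plane.  The incline is drawn once per ring from
    N(incline_mean, incline_sd) clipped to (0, 90]: a shared angular rate
    within a ring keeps the helices from crossing, which independent
    per-fibre rates cannot guarantee at any realistic spread.
    """
    params.validate()
    if z_step <= 0:
        raise ParameterError("z_step must be positive")
    rng = np.random.default_rng(params.seed)
    z = np.arange(0.0, params.length + 0.5 * z_step, z_step)
    if z[-1] < params.length - 1e-9:
        z = np.append(z, params.length)

    fibres: list[FibreCenterline] = []
    rings: list[str] = []
    ring_defs = [
        (RING_OUTER, params.ring_radius_outer, params.n_outer_bundles, 0.0),
        (RING_INNER, params.ring_radius_inner, params.n_inner_bundles, 0.5),
    ]
    for ring, radius, count, stagger in ring_defs:
        if count == 0:
            rng.normal()  # keep the stream position stable across presets
            continue
        delta = float(np.clip(rng.normal(params.incline_mean_deg, params.incline_sd_deg),
                              1e-6, 90.0))
        drad = np.deg2rad(delta)
        # angular rate of the helix: horizontal drift dz/tan(delta) spread
        # tangentially along the ring of this radius
        omega = 0.0 if delta >= 90.0 else 1.0 / (radius * np.tan(drad))
        spacing = 360.0 / count
        base = spacing * (np.arange(count) + stagger)
        theta0 = np.deg2rad(base + rng.normal(0.0, params.azimuth_jitter_deg, count))
        for th0 in theta0:
            theta = th0 + omega * z
            pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
            phi = np.rad2deg(th0 + omega * params.length / 2.0) + 90.0
            fibres.append(FibreCenterline(pts, phi % 360.0, delta))
            rings.append(ring)

    _check_collisions(fibres, rings, params)
    return StemGeometry(params, fibres, rings)


def _check_collisions(fibres: list[FibreCenterline], rings: list[str],
                      params: StemParams) -> None:
    """Raise if any two centerlines come closer than one bundle diameter."""
    if len(fibres) < 2:
        return
    # same ring: constant angular offsets make the closest approach equal
    # to the z=0 separation; across rings the radial gap bounds it below.
    if params.n_outer_bundles > 0 and params.n_inner_bundles > 0:
        gap = abs(params.ring_radius_outer - params.ring_radius_inner)
        if gap < 2 * params.bundle_radius:
            raise GeometryError(
                f"inner and outer rings overlap: radial gap {gap:.3f} mm "
                f"< bundle diameter {2 * params.bundle_radius:.3f} mm"
            )
    starts = np.array([f.points[0, :2] for f in fibres])
    for ring in (RING_OUTER, RING_INNER):
        idx = [i for i, r in enumerate(rings) if r == ring]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                d = float(np.linalg.norm(starts[i] - starts[j]))
                if d < 2 * params.bundle_radius:
                    raise GeometryError(
                        f"bundles {i} and {j} ({ring} ring) overlap: "
                        f"centre distance {d:.3f} mm"
                    )


# ---------------------------------------------------------------------------
# label volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeSpec:
    """Voxel lattice emulating the MRI acquisition geometry.

    Default matches a 168 x 168 x 26 matrix over a 4.2 x 4.2 x 13 mm field
    of view.  ``shape`` is (nx, ny, nz); arrays are stored (z, y, x).
    """

    shape: tuple[int, int, int] = (168, 168, 26)
    field_of_view: tuple[float, float, float] = (4.2, 4.2, 13.0)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ParameterError("shape entries must be positive")
        if any(f <= 0 for f in self.field_of_view):
            raise ParameterError("field of view entries must be positive")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.field_of_view, self.shape))


@dataclass
class LabelVolume:
    """3D label array: 0 background, 1 matrix, 2 inner bundle, 3 outer bundle."""

    data: np.ndarray              # (nz, ny, nx) uint8
    spec: VolumeSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        nx, ny, nz = self.spec.shape
        if self.data.shape != (nz, ny, nx):
            raise ParameterError(
                f"volume data shape {self.data.shape} does not match spec (z,y,x)="
                f"{(nz, ny, nx)}"
            )


def rasterize_label_volume(geometry: StemGeometry, spec: VolumeSpec | None = None) -> LabelVolume:
    """Rasterize a stem geometry into a label volume.

    A voxel is labelled bundle if its centre lies within ``bundle_radius``
    of a centerline (nearest centerline wins; ties by lower fibre index,
    with outer-ring fibres listed first), else matrix on the wall annulus,
    else background.
    """
    spec = spec or VolumeSpec()
    p = geometry.params
    fx, fy, fz = spec.field_of_view
    if 2 * p.outer_radius > fx or 2 * p.outer_radius > fy:
        raise SpatialError(
            f"stem diameter {2 * p.outer_radius} mm exceeds field of view ({fx} x {fy} mm)"
        )
    if p.length < fz - 1e-9:
        raise SpatialError(f"stem length {p.length} mm shorter than axial field of view {fz} mm")

    nx, ny, nz = spec.shape
    vx, vy, vz = spec.voxel_size
    xs = (np.arange(nx) + 0.5) * vx - fx / 2.0
    ys = (np.arange(ny) + 0.5) * vy - fy / 2.0
    zs = (np.arange(nz) + 0.5) * vz
    gx, gy = np.meshgrid(xs, ys)            # (ny, nx)
    rr = np.hypot(gx, gy)
    annulus = (rr >= p.inner_radius) & (rr <= p.outer_radius)

    # outer fibres first so argmin tie-breaking prefers the outer label
    order = [i for i, r in enumerate(geometry.ring_labels) if r == RING_OUTER]
    order += [i for i, r in enumerate(geometry.ring_labels) if r == RING_INNER]
    labels_by_fibre = np.array(
        [LABEL_OUTER_BUNDLE if geometry.ring_labels[i] == RING_OUTER else LABEL_INNER_BUNDLE
         for i in order], dtype=np.uint8)

    data = np.zeros((nz, ny, nx), dtype=np.uint8)
    for iz, zc in enumerate(zs):
        plane = np.where(annulus, LABEL_MATRIX, LABEL_BACKGROUND).astype(np.uint8)
        if order:
            centres = np.array([geometry.fibres[i].xy_at(zc) for i in order])  # (nf, 2)
            d2 = ((gx[..., None] - centres[:, 0]) ** 2
                  + (gy[..., None] - centres[:, 1]) ** 2)                      # (ny, nx, nf)
            nearest = np.argmin(d2, axis=-1)
            hit = np.take_along_axis(d2, nearest[..., None], axis=-1)[..., 0] \
                <= p.bundle_radius ** 2
            plane[hit] = labels_by_fibre[nearest[hit]]
        data[iz] = plane

    meta = {"seed": p.seed, "params": p}
    return LabelVolume(data, spec, meta)


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    parent1_mean: float
    parent1_sd: float
    parent2_mean: float
    parent2_sd: float
    target_h2: float = 0.0

    def validate(self, name: str) -> None:
        if self.parent1_sd <= 0 or self.parent2_sd <= 0:
            raise ParameterError(f"trait {name!r}: parental sds must be positive")
        if not (0.0 <= self.target_h2 < 1.0):
            raise ParameterError(f"trait {name!r}: target_h2 must be in [0, 1)")


@dataclass(frozen=True)
class TraitGenModel:
    traits: dict[str, TraitSpec]
    n_per_parent: int = 50
    n_f2: int = 129
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_parent < 2 or self.n_f2 < 2:
            raise ParameterError("need at least 2 plants per generation")
        for name, t in self.traits.items():
            t.validate(name)


def generate_trait_table(model: TraitGenModel):
    """Draw a two-parent + F2 trait table with additive inheritance.

    Parent rows are N(mean, sd) per line.  F2 rows are
    midparent + N(0, V_G) + N(0, V_E) with the environmental variance
    estimated as the geometric mean of the parental variances,
    V_E = sqrt(V_P1 * V_P2), and V_G = V_E * h2 / (1 - h2), so that the
    broad-sense heritability of the generated population equals
    ``target_h2`` in expectation.  Dominance is deliberately absent.
    """
    import pandas as pd

    model.validate()
    rng = np.random.default_rng(model.seed)
    n1 = n2 = model.n_per_parent
    generation = ["P1"] * n1 + ["P2"] * n2 + ["F2"] * model.n_f2
    out = {"plant_id": [f"{g}_{i:04d}" for i, g in enumerate(generation)],
           "generation": generation}
    for name, t in model.traits.items():
        p1 = rng.normal(t.parent1_mean, t.parent1_sd, n1)
        p2 = rng.normal(t.parent2_mean, t.parent2_sd, n2)
        v_e = t.parent1_sd * t.parent2_sd                 # sqrt(V_P1 * V_P2)
        v_g = v_e * t.target_h2 / (1.0 - t.target_h2)
        mid = 0.5 * (t.parent1_mean + t.parent2_mean)
        f2 = (mid
              + rng.normal(0.0, np.sqrt(v_g), model.n_f2)
              + rng.normal(0.0, np.sqrt(v_e), model.n_f2))
        out[name] = np.concatenate([p1, p2, f2])
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# component library and spectra
# ---------------------------------------------------------------------------

@dataclass
class ComponentLibrary:
    """Reference spectra of cell-wall components on a common wavenumber grid."""

    wavenumbers: np.ndarray       # descending, cm-1
    names: list[str]
    spectra: np.ndarray           # (n_components, n_points), nonnegative
    baseline_order: int = 2
    version: int = 0

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (len(self.names), self.wavenumbers.size):
            raise LibraryError("spectra matrix shape does not match names/grid")
        if not np.all(np.isfinite(self.spectra)) or np.any(self.spectra < 0):
            raise LibraryError("reference spectra must be finite and nonnegative")
        if np.linalg.matrix_rank(self.spectra) < len(self.names):
            raise LibraryError("component library is rank deficient")

    @property
    def n_components(self) -> int:
        return len(self.names)

    @classmethod
    def from_band_config(cls, config: dict) -> "ComponentLibrary":
        g = config["grid"]
        wn = np.arange(g["high_cm1"], g["low_cm1"] - g["step_cm1"] / 2, -g["step_cm1"],
                       dtype=float)
        names, rows = [], []
        for name, spec in config["components"].items():
            s = np.zeros_like(wn)
            for b in spec["bands"]:
                s += b["height"] * np.exp(-0.5 * ((wn - b["center"]) / b["width"]) ** 2)
            names.append(name)
            rows.append(s)
        return cls(wn, names, np.array(rows),
                   baseline_order=config.get("baseline_order", 2),
                   version=config.get("version", 0))

    @classmethod
    def default(cls) -> "ComponentLibrary":
        ref = importlib.resources.files("culmforce") / "data" / "component_bands.yaml"
        return cls.from_band_config(yaml.safe_load(ref.read_text()))


@dataclass
class SpectrumSet:
    """A batch of absorbance spectra plus generation ground truth."""

    wavenumbers: np.ndarray       # (m,)
    absorbance: np.ndarray        # (n_samples, m)
    component_names: list[str] | None = None
    true_concentrations: np.ndarray | None = None
    sample_ids: list[str] | None = None
    groups: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]


def generate_spectra(library: ComponentLibrary, concentrations,
                     noise_sd: float = 0.0, seed: int = 0,
                     baseline_sd: float = 0.0) -> SpectrumSet:
    """Mix reference spectra into noisy sample spectra.

    Each spectrum is ``sum_i c_i K_i`` plus a random low-order baseline
    polynomial (coefficients N(0, baseline_sd)) plus i.i.d. Gaussian noise.
    True concentrations are recorded on the returned set.
    """
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if c.shape[1] != library.n_components:
        raise ParameterError(
            f"weights per sample must have length {library.n_components}, got {c.shape[1]}"
        )
    if np.any(c < 0):
        raise ParameterError("component weights must be nonnegative")
    if noise_sd < 0 or baseline_sd < 0:
        raise ParameterError("noise_sd and baseline_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    y = c @ library.spectra
    if baseline_sd > 0:
        x = np.linspace(-1.0, 1.0, library.wavenumbers.size)
        basis = np.vander(x, library.baseline_order + 1, increasing=True)  # (m, k+1)
        coeffs = rng.normal(0.0, baseline_sd, (c.shape[0], library.baseline_order + 1))
        y = y + coeffs @ basis.T
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    ids = [f"s{i:04d}" for i in range(c.shape[0])]
    return SpectrumSet(library.wavenumbers.copy(), y, list(library.names), c, ids)
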