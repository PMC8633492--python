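"""FTIR chemotyping: preprocessing, component decomposition, PCA, screening.

The decomposition fits each spectrum by ordinary least squares against an
explicit design of baseline polynomial columns plus component reference
spectra (the EMSC convention).  Loadings may be negative and are reported
as-is; a nonnegative fit is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DegenerateError, LibraryError, ParameterError, RangeError
from .synthetic_data import ComponentLibrary, SpectrumSet


@dataclass
class Spectrum:
    """One absorbance spectrum with its preprocessing state."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    flags: dict = field(default_factory=lambda: {
        "truncated": False, "vector_normalized": False,
        "minmax_normalized": False, "degenerate": False,
    })

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ParameterError("wavenumber and absorbance arrays must match")
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ParameterError("wavenumbers must be strictly monotonic")


@dataclass
class ComponentLoadings:
    """Least-squares loadings of one spectrum against a component library."""

    loadings: dict[str, float]
    baseline_coefficients: np.ndarray
    residual_rms: float
    negative_flagged: bool

    @property
    def lignin_s_over_g(self) -> float:
        """Syringyl- over guaiacyl-rich lignin loading ratio (NaN if undefined)."""
        g = self.loadings.get("lignin_G")
        s = self.loadings.get("lignin_S")
        if g is None or s is None or g == 0.0:
            return float("nan")
        return s / g

    @property
    def xylan_share(self) -> float:
        """Xylan fraction of the summed hemicellulose loadings (NaN if absent)."""
        hemi = {k: v for k, v in self.loadings.items() if k.startswith("hemicellulose")}
        total = sum(hemi.values())
        if "hemicellulose_xylan" not in hemi or total == 0.0:
            return float("nan")
        return hemi["hemicellulose_xylan"] / total


def preprocess_spectrum(raw: Spectrum, lo: float = 800.0, hi: float = 1800.0,
                        mode: str = "vector") -> Spectrum:
    """Truncate to [lo, hi] and normalize.

    ``mode`` is one of ``vector`` (unit L2 norm), ``minmax`` (range [0, 1])
    or ``both``.  A constant spectrum cannot be min-max scaled; it is
    returned as zeros with a degenerate flag and a warning.
    """
    if mode not in ("vector", "minmax", "both"):
        raise ParameterError(f"unknown normalization mode {mode!r}")
    wn, ab = raw.wavenumbers, raw.absorbance
    if wn.min() > lo or wn.max() < hi:
        raise RangeError(
            f"spectrum covers [{wn.min():g}, {wn.max():g}] cm-1, "
            f"requested [{lo:g}, {hi:g}]"
        )
    keep = (wn >= lo) & (wn <= hi)
    wn, ab = wn[keep], ab[keep].copy()
    flags = dict(raw.flags)
    flags["truncated"] = True
    if mode in ("vector", "both"):
        norm = np.linalg.norm(ab)
        if norm == 0.0:
            flags["degenerate"] = True
            warnings.warn("zero spectrum cannot be vector normalized", stacklevel=2)
        else:
            ab = ab / norm
        flags["vector_normalized"] = True
    if mode in ("minmax", "both"):
        rng = ab.max() - ab.min()
        if rng == 0.0:
            flags["degenerate"] = True
            ab = np.zeros_like(ab)
            warnings.warn("constant spectrum has no min-max range; returning zeros",
                          stacklevel=2)
        else:
            ab = (ab - ab.min()) / rng
        flags["minmax_normalized"] = True
    return Spectrum(wn, ab, flags)


def _baseline_basis(n_points: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_points)
    return np.vander(x, order + 1, increasing=True)      # (m, order + 1)


def _align_library(lib: ComponentLibrary, wavenumbers: np.ndarray) -> np.ndarray:
    """Library matrix (k, m) interpolated onto the spectrum grid."""
    if wavenumbers.size == lib.wavenumbers.size and np.allclose(wavenumbers, lib.wavenumbers):
        return lib.spectra
    lo, hi = lib.wavenumbers.min(), lib.wavenumbers.max()
    if wavenumbers.min() < lo - 1e-9 or wavenumbers.max() > hi + 1e-9:
        raise AlignmentError(
            f"spectrum grid [{wavenumbers.min():g}, {wavenumbers.max():g}] extends "
            f"beyond the library grid [{lo:g}, {hi:g}]; refusing to extrapolate"
        )
    # np.interp wants ascending x
    asc = lib.wavenumbers[::-1]
    return np.array([np.interp(wavenumbers, asc, s[::-1]) for s in lib.spectra])


def emsc_decompose(s: Spectrum, lib: ComponentLibrary,
                   baseline_order: int | None = None,
                   nonnegative: bool = False) -> ComponentLoadings:
    """Decompose a spectrum into baseline + component reference loadings.

    Ordinary least squares against ``[polynomial basis | references]``.
    Coefficients may be negative and are reported as-is (flagged); pass
    ``nonnegative=True`` to constrain component loadings to >= 0.
    """
    order = lib.baseline_order if baseline_order is None else baseline_order
    k = _align_library(lib, s.wavenumbers)               # (k, m)
    basis = _baseline_basis(s.wavenumbers.size, order)   # (m, order+1)
    design = np.hstack([basis, k.T])                     # (m, order+1+k)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise LibraryError("rank-deficient design: components + baseline are collinear")
    if nonnegative:
        from scipy.optimize import lsq_linear
        n_b = basis.shape[1]
        lb = np.concatenate([np.full(n_b, -np.inf), np.zeros(lib.n_components)])
        res = lsq_linear(design, s.absorbance, bounds=(lb, np.full(design.shape[1], np.inf)))
        coef = res.x
    else:
        coef, *_ = np.linalg.lstsq(design, s.absorbance, rcond=None)
    resid = s.absorbance - design @ coef
    n_b = basis.shape[1]
    loadings = dict(zip(lib.names, coef[n_b:]))
    return ComponentLoadings(
        loadings=loadings,
        baseline_coefficients=coef[:n_b],
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        negative_flagged=bool(any(v < 0 for v in loadings.values())),
    )


def decompose_set(spectra: SpectrumSet, lib: ComponentLibrary, **kwargs):
    """Decompose every spectrum of a set; returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i in range(spectra.n_samples):
        s = Spectrum(spectra.wavenumbers, spectra.absorbance[i])
        ld = emsc_decompose(s, lib, **kwargs)
        row = dict(ld.loadings)
        row["residual_rms"] = ld.residual_rms
        row["lignin_s_over_g"] = ld.lignin_s_over_g
        row["sample_id"] = (spectra.sample_ids[i] if spectra.sample_ids else f"s{i:04d}")
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def pca_chemotype(spectra: SpectrumSet | np.ndarray, n_components: int = 2):
    """Centered PCA scores of a preprocessed spectrum set.

    Returns ``(scores, explained_variance_ratio, loadings)``.  Sign
    convention: the largest-magnitude loading of each component is made
    positive, so scores are deterministic.  Constant (zero-variance) data
    is flagged by zero explained variance.
    """
    x = spectra.absorbance if isinstance(spectra, SpectrumSet) else np.asarray(spectra, float)
    n, m = x.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 spectra")
    if n_components > min(n, m):
        raise ParameterError(
            f"requested {n_components} components from {n} spectra of length {m}"
        )
    xc = x - x.mean(axis=0)
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((sv ** 2).sum())
    # guard against rounding residue of constant data masquerading as variance
    scale = float((x ** 2).sum()) or 1.0
    if total <= 1e-24 * scale:
        total = 0.0
    evr = (sv[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    loadings = vt[:n_components]
    scores = u[:, :n_components] * sv[:n_components]
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    return scores, evr, loadings


def effect_screen(loadings_a, loadings_b) -> "pd.DataFrame":  # noqa: F821
    """Per-component Cohen's D between two groups of loadings tables.

    Accepts DataFrames (or dicts of arrays) whose columns are component
    loadings; returns D and the threshold class per component.
    """
    import pandas as pd

    from .traits import cohens_d

    a = pd.DataFrame(loadings_a)
    b = pd.DataFrame(loadings_b)
    common = [c for c in a.columns if c in b.columns
              and np.issubdtype(a[c].dtype, np.number)]
    rows = []
    for c in common:
        try:
            es = cohens_d(a[c].to_numpy(), b[c].to_numpy())
            rows.append({"component": c, "D": es.d, "class": es.effect_class})
        except DegenerateError:
            rows.append({"component": c, "D": float("nan"), "class": "degenerate"})
    return pd.DataFrame(rows).set_index("component")
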