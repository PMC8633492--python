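"""Named parameter presets for the demo pipelines.

Geometry presets encode the qualitative resistant-versus-prone contrasts:
the resistant rye culm is thinner but carries more outer bundles (27 vs 19,
the rounded printed means) at a higher degree of incline (larger tilt away
from vertical; plane-referenced incline 75 vs 85 degrees).  Inner-ring
counts are equal (11).  Wall radii, ring radii and incline values are
plausible stand-ins chosen so the stems fit the default MRI-like field of
view; no numeric incline is claimed beyond the ordering.  Trait presets
carry the printed parental means/sds for plant height and culm dry weight.
"""

from __future__ import annotations

from .errors import ParameterError
from .synthetic_data import StemParams, TraitGenModel, TraitSpec, VolumeSpec

_STEMS = {
    "rye_resistant": StemParams(
        outer_radius=1.8, inner_radius=1.3, length=20.0,
        n_outer_bundles=27, n_inner_bundles=11,
        ring_radius_outer=1.65, ring_radius_inner=1.42,
        bundle_radius=0.07,
        incline_mean_deg=75.0, incline_sd_deg=1.5, azimuth_jitter_deg=1.5,
    ),
    "rye_prone": StemParams(
        outer_radius=2.05, inner_radius=1.40, length=20.0,
        n_outer_bundles=19, n_inner_bundles=11,
        ring_radius_outer=1.85, ring_radius_inner=1.55,
        bundle_radius=0.07,
        incline_mean_deg=85.0, incline_sd_deg=1.5, azimuth_jitter_deg=1.5,
    ),
    # the wheat lines are semi-dwarf with thicker walls; resistant has more
    # bundles in both rings but a similar incline
    "wheat_resistant": StemParams(
        outer_radius=1.9, inner_radius=1.15, length=20.0,
        n_outer_bundles=24, n_inner_bundles=14,
        ring_radius_outer=1.70, ring_radius_inner=1.35,
        bundle_radius=0.07,
        incline_mean_deg=80.0, incline_sd_deg=1.5, azimuth_jitter_deg=1.5,
    ),
    "wheat_prone": StemParams(
        outer_radius=1.75, inner_radius=1.15, length=20.0,
        n_outer_bundles=18, n_inner_bundles=10,
        ring_radius_outer=1.58, ring_radius_inner=1.32,
        bundle_radius=0.07,
        incline_mean_deg=81.0, incline_sd_deg=1.5, azimuth_jitter_deg=1.5,
    ),
}

#: printed parental trait distributions used as generator inputs
_TRAITS = {
    "rye": TraitGenModel(
        traits={
            # resistant parent first (P1)
            "plant_height_cm": TraitSpec(110.7, 6.9, 95.0, 15.2, target_h2=0.6),
            "culm_dry_weight_g": TraitSpec(13.7, 5.0, 1.7, 1.6, target_h2=0.6),
        },
        n_per_parent=50, n_f2=129,
    ),
}

PRESET_NAMES = tuple(_STEMS)


def stem_params(name: str, seed: int | None = None) -> StemParams:
    if name not in _STEMS:
        raise ParameterError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    p = _STEMS[name]
    if seed is not None:
        from dataclasses import replace
        p = replace(p, seed=seed)
    return p


def volume_spec(name: str) -> VolumeSpec:
    """MRI-like acquisition lattice; one size fits all presets."""
    if name not in _STEMS:
        raise ParameterError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    p = _STEMS[name]
    fov_xy = 4.2
    if 2 * p.outer_radius >= fov_xy:
        fov_xy = 2 * p.outer_radius + 0.5
    return VolumeSpec(shape=(168, 168, 26), field_of_view=(fov_xy, fov_xy, 13.0))


def trait_model(crop: str = "rye", seed: int | None = None) -> TraitGenModel:
    if crop not in _TRAITS:
        raise ParameterError(f"no trait preset for {crop!r}")
    m = _TRAITS[crop]
    if seed is not None:
        from dataclasses import replace
        m = replace(m, seed=seed)
    return m
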