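"""Deterministic stem parameter sets used by several test modules."""

from culmforce.synthetic_data import StemParams


def vertical_preset(**overrides) -> StemParams:
    base = dict(outer_radius=1.8, inner_radius=1.3, length=20.0,
                n_outer_bundles=27, n_inner_bundles=11,
                ring_radius_outer=1.65, ring_radius_inner=1.42,
                bundle_radius=0.07, incline_mean_deg=90.0,
                incline_sd_deg=0.0, azimuth_jitter_deg=0.0, seed=0)
    base.update(overrides)
    return StemParams(**base)


def symmetric_preset(**overrides) -> StemParams:
    """Rotationally symmetric layout with identical inclines in each ring."""
    return vertical_preset(incline_mean_deg=75.0, **overrides)
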