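"""Shared test helpers."""

from exudate import PhantomSpec


def small_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A 256x256 phantom spec with geometry scaled to the smaller frame,
    for tests that do not need the full working resolution."""
    base = dict(
        size=(256, 256),
        od_radius_range=(14.0, 20.0),
        exudate_area_range=(8.0, 500.0),
        soft_radius_range=(4.0, 8.0),
        n_exudates=4,
    )
    base.update(overrides)
    return PhantomSpec(seed=seed, **base)
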