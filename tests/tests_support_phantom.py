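"""Small cached phantoms shared by unit tests (64³, 3 levels — fast)."""

from vmi.phantom import PhantomSpec, make_phantom

_cache: dict = {}


def quick_phantom(seed: int, **overrides):
    """(volume, truth mask) of a small 64³ phantom; cached per (seed, overrides)."""
    key = (seed, tuple(sorted(overrides.items())))
    if key not in _cache:
        spec = PhantomSpec(
            shape=(64, 64, 64),
            spacing=(10.0, 10.0, 10.0),
            levels=3,
            root_diameter=60.0,
            branch_length_ratio=5.0,
            seed=seed,
            **overrides,
        )
        volume, mask, _tree = make_phantom(spec)
        _cache[key] = (volume, mask)
    return _cache[key]
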