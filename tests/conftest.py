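import warnings

import numpy as np
import pytest

from vasq.phantom import PhantomSpec, generate_phantom
from vasq.skeleton import prune_spurs, skeletonize
from vasq.topology import build_graph, classify_levels, detect_root

_BUNDLE_CACHE = {}


def phantom_bundle(seed=0, **kw):
    """Memoized phantom generation (bundles are reused across tests)."""
    key = (seed, tuple(sorted(kw.items())))
    if key not in _BUNDLE_CACHE:
        _BUNDLE_CACHE[key] = generate_phantom(PhantomSpec(seed=seed, **kw))
    return _BUNDLE_CACHE[key]


def analyzed_graph(bundle):
    """Run skeleton + topology on a bundle's ground-truth mask."""
    skel = prune_spurs(skeletonize(bundle.truth_mask), 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = build_graph(skel, bundle.truth_mask, bundle.spec.pixel_pitch_um)
    root = detect_root(graph)
    classify_levels(graph, root)
    return graph, root


@pytest.fixture(scope="session")
def clean_bundle():
    """A default-geometry, noise-free phantom."""
    return phantom_bundle(seed=0, noise_sd_gray=0.0)


@pytest.fixture(scope="session")
def noisy_bundle():
    """A phantom at the default (noisy) imaging conditions."""
    return phantom_bundle(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def vessel_patch(bundle, rng, size=128, min_fg=0.02):
    """Crop a patch containing vessel pixels from a bundle."""
    fg = np.argwhere(bundle.truth_mask == 1)
    for _ in range(100):
        r, c = fg[rng.integers(len(fg))]
        r0 = int(np.clip(r - size // 2, 0, bundle.truth_mask.shape[0] - size))
        c0 = int(np.clip(c - size // 2, 0, bundle.truth_mask.shape[1] - size))
        m = bundle.truth_mask[r0 : r0 + size, c0 : c0 + size]
        if m.mean() > min_fg:
            return bundle.bright_field[r0 : r0 + size, c0 : c0 + size], m
    raise RuntimeError("no vessel patch found")
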