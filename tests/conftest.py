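"""Shared fixtures: small synthetic slides and patch sets.

Session-scoped fixtures keep generation cost down; tests must not mutate
them in place.
"""

from __future__ import annotations

import numpy as np
import pytest

from gastroslide.patch_model import train_reference_classifier
from gastroslide.synthdata import (
    SlideSpec,
    generate_patch_set,
    generate_synthetic_slide,
)


def square(x0: float, y0: float, side: float) -> np.ndarray:
    return np.array(
        [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]],
        dtype=float,
    )


@pytest.fixture(scope="session")
def demo_spec() -> SlideSpec:
    """A 512x512 slide: normal sheet with one cancer lesion, white rim."""
    return SlideSpec(
        width=512,
        height=512,
        lesion_polygons=[
            ("normal", square(16, 16, 480)),
            ("cancer", square(272, 272, 224)),
        ],
        seed=42,
    )


@pytest.fixture(scope="session")
def demo_slide(demo_spec):
    return generate_synthetic_slide(demo_spec)


@pytest.fixture(scope="session")
def patch_set():
    """Balanced 3-class patch set, 40 per class, 96 px."""
    return generate_patch_set(40, patch_size=96, seed=11)


@pytest.fixture(scope="session")
def eval_patch_set():
    """Held-out patch set from an independent seed."""
    return generate_patch_set(20, patch_size=96, seed=1213)


@pytest.fixture(scope="session")
def trained_classifier(patch_set):
    return train_reference_classifier(patch_set, seed=0)
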