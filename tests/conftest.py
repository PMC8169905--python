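"""Shared fixtures: small synthetic images generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from hairmorph import CalibratedImage, simulate_arc_image, simulate_ellipse_image

#: canvas large enough for 25 disjoint fragments at any study curvature,
#: small enough to keep the suite fast
SMALL_ARC_CANVAS = (1950, 2600)
SMALL_ELLIPSE_CANVAS = (700, 700)


@pytest.fixture(scope="session")
def arc_image_factory():
    def make(curvature=1.0, n_fragments=25, seed=0, image_id="arc", canvas=SMALL_ARC_CANVAS):
        return simulate_arc_image(
            curvature,
            n_fragments=n_fragments,
            canvas_px=canvas,
            resolution_px_per_mm=132.0,
            seed=seed,
            image_id=image_id,
        )

    return make


@pytest.fixture(scope="session")
def ellipse_image_factory():
    def make(spec=None, seed=0, image_id="ellipse", canvas=SMALL_ELLIPSE_CANVAS):
        return simulate_ellipse_image(
            spec, canvas_px=canvas, resolution_px_per_um=4.25, seed=seed, image_id=image_id
        )

    return make


@pytest.fixture()
def blank_image():
    return CalibratedImage(np.full((200, 200), 255, np.uint8), resolution=132.0, image_id="blank")
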