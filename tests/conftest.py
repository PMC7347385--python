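"""Shared fixtures: a small synthetic mouse session and its tracking run."""

from __future__ import annotations

import numpy as np
import pytest

from stringpull.segmentation import ColorModel, mask_range
from stringpull.synthetic import SyntheticSpec, modeled_mouse
from stringpull.tracking import run_tracking


def make_small_spec(n_frames: int = 60, tilt: float = 3.0,
                    seed: int = 0) -> SyntheticSpec:
    """Half-scale mouse (240x240, 70 px body = 70 mm) for fast tests."""
    return SyntheticSpec(
        height=240, width=240, n_frames=n_frames, px_per_mm=1.0, seed=seed,
        body_center=(120.0, 140.0), body_axes=(35.0, 20.0),
        tilt_amp_deg=tilt,
        ear_dx=14.0, ear_row=97.0, ear_axes=(5.0, 4.0),
        nose_row=85.0, nose_axes=(4.0, 3.0),
        hand_dx=38.0, hand_row=80.0, hand_axes=(5.5, 4.5),
        hand_amp_y=30.0, hand_amp_x=8.0,
    )


def color_models(spec: SyntheticSpec) -> dict[str, ColorModel]:
    return {k: ColorModel(k, [spec.colors[k]])
            for k in ("fur", "ears", "nose", "hands")}


def mask_provider(stack, models):
    def provider(t):
        frame = stack.frame(t)
        return {k: mask_range(frame, m) for k, m in models.items()}

    return provider


@pytest.fixture(scope="session")
def small_session():
    """A 60-frame half-scale mouse video, its truth, and a tracking run."""
    spec = make_small_spec(n_frames=60)
    stack, truth = modeled_mouse(spec)
    models = color_models(spec)
    provider = mask_provider(stack, models)
    init = {"hand_R": truth.part_xy("hand_R", 0),
            "hand_L": truth.part_xy("hand_L", 0)}
    track = run_tracking(provider, stack.n_frames, stack.px_per_mm, init)
    return {"spec": spec, "stack": stack, "truth": truth, "models": models,
            "provider": provider, "track": track}
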