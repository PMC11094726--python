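"""Color mapping for atom attributions.

Positive attributions (toward the toxic class) map to red, negative to blue,
zero to white, interpolated in RGB.  Intensity is scaled to the maximum
absolute atom attribution of the rendered data set, and every attribution at
or above ``clip_fraction`` (default 70%) of that maximum receives full
intensity so that the lower range stays discriminable.  Input-level and
hidden-level explanations use separate scales, since unmatched neurons make
hidden-level magnitudes systematically smaller.

Only the numeric color computation lives here; rendering the molecule itself
is left to any RDKit drawing pipeline the user prefers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["ColorScale", "atom_color", "scale_for"]


@dataclass
class ColorScale:
    dataset_max: float  # max |atom attribution| over the rendered set
    clip_fraction: float = 0.7

    def __post_init__(self):
        if self.dataset_max <= 0:
            raise ValueError("dataset_max must be positive")
        if not 0 < self.clip_fraction <= 1:
            raise ValueError("clip_fraction must be in (0, 1]")


def scale_for(atom_value_sets: Iterable[Sequence[float]], clip_fraction: float = 0.7) -> ColorScale:
    """One scale per method, from the maximum |attribution| across a data set."""
    m = max((abs(v) for vals in atom_value_sets for v in vals), default=0.0)
    return ColorScale(dataset_max=m, clip_fraction=clip_fraction)


def atom_color(value: float, scale: ColorScale) -> tuple[float, float, float]:
    """RGB triple in [0,1]: white at 0, red hue positive, blue hue negative;
    intensity saturates at ``clip_fraction * dataset_max``."""
    intensity = min(abs(value) / (scale.clip_fraction * scale.dataset_max), 1.0)
    fade = 1.0 - intensity
    if value >= 0:
        return (1.0, fade, fade)
    return (fade, fade, 1.0)
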