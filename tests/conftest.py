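import numpy as np
import pytest
from hypothesis import settings

from mcht.geometry import DEFAULT_GEOMETRY, px_to_deg

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


class StepResponder:
    """Noise-free monotone responder: seen iff elevation ≤ boundary."""

    def __init__(self, boundary_deg: float):
        self.boundary_deg = boundary_deg

    def respond(self, azimuth_deg: float, elevation_deg: float) -> bool:
        return elevation_deg <= self.boundary_deg


class ConstantResponder:
    def __init__(self, seen: bool):
        self.seen = seen

    def respond(self, azimuth_deg: float, elevation_deg: float) -> bool:
        return self.seen


def scan_transition_deg(responder, azimuth_deg, geometry=DEFAULT_GEOMETRY):
    """Brute-force oracle: present every pixel row from fixation upward and
    return the midpoint between the last seen and first unseen row."""
    extent = geometry.elevation_extent_px
    seen = [responder.respond(azimuth_deg, px_to_deg(px, geometry))
            for px in range(extent + 1)]
    if all(seen):
        return geometry.elevation_max_deg
    if not seen[0]:
        return 0.0
    first_unseen = seen.index(False)
    return px_to_deg(first_unseen - 0.5, geometry)


@pytest.fixture
def geometry():
    return DEFAULT_GEOMETRY
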