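"""Shared fixtures: desk-scale acquisition geometries and synthetic stacks."""

import pytest

from minwaves.geometry import DropletGeometry, StackGeometry


@pytest.fixture
def wave_geometry() -> StackGeometry:
    """Field large enough to hold >= 2.8 wavelengths of a 113-um wave."""
    return StackGeometry(
        n_frames=60, height=320, width=320, pixel_size_um=1.0, frame_interval_s=2.0
    )


@pytest.fixture
def standing_geometry() -> StackGeometry:
    """>= 3.6 periods of a 105-s oscillation in the time record."""
    return StackGeometry(
        n_frames=128, height=96, width=96, pixel_size_um=1.0, frame_interval_s=3.0
    )


@pytest.fixture
def droplet_setup() -> tuple[DropletGeometry, StackGeometry]:
    """Droplet rim plus a record long enough for >= 3 patch revolutions."""
    geom = StackGeometry(
        n_frames=240, height=128, width=128, pixel_size_um=0.5, frame_interval_s=3.0
    )
    droplet = DropletGeometry(center=(63.5, 63.5), radius_um=10.0, rim_width_um=3.0)
    return droplet, geom
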