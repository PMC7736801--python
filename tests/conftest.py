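import numpy as np
import pytest

from dropread import (
    ChannelComponents,
    IntensityModel,
    OccupancyCall,
    default_intensity_model,
)


@pytest.fixture(scope="session")
def default_model() -> IntensityModel:
    return default_intensity_model()


@pytest.fixture(scope="session")
def separated_model() -> IntensityModel:
    """Two-channel model with widely separated, equal-scale components."""
    comp = ChannelComponents(2.0, 0.1, 3.2, 0.1)
    return IntensityModel(components={"ch1": comp, "ch2": comp})


def draw_mixture(
    comp: ChannelComponents, weight_occupied: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Linear intensities and occupancy labels from a known two-component model."""
    rng = np.random.default_rng(seed)
    occupied = rng.random(n) < weight_occupied
    loc = np.where(occupied, comp.occupied_loc, comp.unoccupied_loc)
    scale = np.where(occupied, comp.occupied_scale, comp.unoccupied_scale)
    return 10.0 ** (loc + scale * rng.standard_normal(n)), occupied


def calls_from_flags(flags: list[dict[str, bool]]) -> list[OccupancyCall]:
    """OccupancyCall list from per-droplet channel booleans (posterior 0/1)."""
    return [
        OccupancyCall(
            index=i,
            posterior={ch: 1.0 if v else 0.0 for ch, v in f.items()},
            occupied=dict(f),
        )
        for i, f in enumerate(flags)
    ]
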