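import numpy as np
import pytest

from mbscreen.plates import Measurement, PlateSet, WellAddress, WellRole, default_layout


def build_plate_set(
    test_signals: dict[str, float],
    neg_signal: float = 10_000.0,
    pos_signal: float = 500.0,
    plate_id: str = "p1",
    cell_model: str = "modelA",
    layout=None,
    min_controls: int = 8,
) -> PlateSet:
    """One-plate PlateSet: given per-compound test signals, constant controls."""
    layout = layout or default_layout()
    test_wells = sorted(w for w, r in layout.items() if r is WellRole.TEST)
    measurements = []
    for well, (cid, sig) in zip(test_wells, test_signals.items()):
        measurements.append(Measurement(plate_id, well, cid, 5.0, 1, sig))
    for well, role in layout.items():
        if role is WellRole.NEG_CONTROL:
            measurements.append(Measurement(plate_id, well, "DMSO", None, 1, neg_signal))
        elif role is WellRole.POS_CONTROL:
            measurements.append(Measurement(plate_id, well, "bortezomib", None, 1, pos_signal))
    return PlateSet(measurements, layout=layout, cell_model=cell_model,
                    min_controls=min_controls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
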