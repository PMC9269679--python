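import numpy as np
import pytest

from gaitpartition import (
    GaitRecording,
    Hint,
    SignalTrace,
    SyntheticGaitSpec,
    generate_recording,
)


@pytest.fixture(scope="session")
def default_recording() -> GaitRecording:
    """The reference synthetic trial: 20 landings per side, seed 1."""
    return generate_recording(SyntheticGaitSpec(n_steps=20, seed=1))


@pytest.fixture(scope="session")
def small_recording() -> GaitRecording:
    return generate_recording(SyntheticGaitSpec(n_steps=3, seed=7))


def first_swing_hint(rec: GaitRecording, channel: str = "acc_foot_r",
                     side: str = "right", polarity: str = "auto") -> Hint:
    """Hint covering the first ground-truth swing phase of a recording."""
    ev = rec.truth_events[side]
    return Hint(
        channel=channel,
        start_s=ev.foot_offs_s[0],
        end_s=ev.foot_contacts_s[1],
        polarity=polarity,
    )


def sine_trace(freq_hz: float, rate_hz: float = 100.0, duration_s: float = 5.0,
               amplitude: float = 1.0, name: str = "sine") -> SignalTrace:
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    return SignalTrace(name, rate_hz, amplitude * np.sin(2 * np.pi * freq_hz * t))
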