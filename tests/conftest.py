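import numpy as np
import pytest

from e4physio import (
    ArtifactEpoch,
    MovementBurst,
    ScrEvent,
    SignalStream,
    SynthSpec,
    synth_session,
)


@pytest.fixture
def quiet_spec() -> SynthSpec:
    """A short quiet resting recording, no injected events."""
    return SynthSpec(duration=120.0, seed=11)


@pytest.fixture
def eventful_spec() -> SynthSpec:
    """Two SCRs, one spike artifact, one movement burst."""
    return SynthSpec(
        duration=300.0,
        seed=7,
        scr_events=(
            ScrEvent(time=50.0, amplitude=0.4),
            ScrEvent(time=150.0, amplitude=0.2),
        ),
        artifact_epochs=(ArtifactEpoch(index=48, kind="spike"),),
        movement_bursts=(MovementBurst(start=200.0, end=230.0, mean_g=1.2),),
    )


@pytest.fixture
def eventful_session(eventful_spec):
    session, truth = synth_session(eventful_spec)
    return session, truth


def constant_stream(value: float, duration: float, fs: float = 4.0,
                    start: float = 1581000000.0) -> SignalStream:
    n = int(round(duration * fs))
    return SignalStream(
        start_unix=start,
        fs=fs,
        samples=np.full((n, 1), value),
        channel_names=("eda",),
        units=("uS",),
    )
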