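import pytest

from soundstates import simulate as sim
from soundstates.protocol import (
    StimulusSet,
    SoundStimulus,
    build_session_schedule,
    build_stimulus_set,
)


@pytest.fixture(scope="session")
def stimulus_set() -> StimulusSet:
    return build_stimulus_set(seed=0)


@pytest.fixture(scope="session")
def schedule(stimulus_set):
    return build_session_schedule(stimulus_set, seed=0)


@pytest.fixture(scope="session")
def tone_set(stimulus_set) -> StimulusSet:
    """Reduced battery: the 28 pure tones only."""
    return StimulusSet(tuple(stimulus_set.by_category("pure_tone")))


@pytest.fixture()
def single_tone() -> StimulusSet:
    tone = SoundStimulus(0, "pure_tone", 70.0, 0.25, {"frequencies_khz": [8.0]})
    return StimulusSet((tone,))


def make_unit(
    unit_id=0,
    recording_id=0,
    remodel_class="no_change",
    spont=(5.0, 5.0),
    bf=8.0,
    hw=(0.4, 0.4),
    gain=(20.0, 20.0),
    threshold=(45.0, 45.0),
    latency=0.005,
) -> sim.NeuronGroundTruth:
    """Hand-built ground-truth unit for targeted tests."""
    return sim.NeuronGroundTruth(
        unit_id=unit_id,
        recording_id=recording_id,
        remodel_class=remodel_class,
        wake=sim.StateParams(spont[0], bf, hw[0], gain[0], threshold[0], latency),
        anesthesia=sim.StateParams(spont[1], bf, hw[1], gain[1], threshold[1], latency),
    )


@pytest.fixture()
def unit_factory():
    return make_unit
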