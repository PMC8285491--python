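import pytest
from hypothesis import HealthCheck, settings

from dyadrank.ethogram_io import (
    Animal,
    Behavior,
    EventRecord,
    PushOutcome,
    TestCode,
)

TestCode.__test__ = False  # enum, not a test class; silence collection

# the ev fixture is a stateless factory, safe to share across generated
# examples; derandomize for reproducible CI-free runs
settings.register_profile(
    "dyadrank",
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("dyadrank")


@pytest.fixture
def ev():
    """Terse EventRecord factory with sensible defaults."""

    def make(
        t_start,
        t_stop,
        animal="A",
        behavior="consumption",
        outcome=None,
        pellets=None,
        test="WC",
        day=1,
        pair="p1",
        trial=None,
    ):
        if behavior == "pushing" and outcome is None:
            outcome = "successful"
        return EventRecord(
            pair_id=pair,
            test_code=TestCode(test),
            day=day,
            animal_id=Animal(animal),
            behavior=Behavior(behavior),
            outcome=None if outcome is None else PushOutcome(outcome),
            t_start=float(t_start),
            t_stop=float(t_stop),
            pellets=pellets,
            trial=trial,
        )

    return make
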