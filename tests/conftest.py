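import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_run():
    """One-cell scene with three planted events, fully normalized."""
    from astroca.pipeline import process_recording
    from astroca.scenarios import small_scene

    movie, geom, gt, hill = small_scene(seed=0)
    res = process_recording(movie, None, hill, f0_window=40)
    return movie, geom, gt, hill, res


@pytest.fixture(scope="session")
def validation_run():
    """Full-scale validation movie (crosstalk, 10 events) through the pipeline."""
    from astroca.pipeline import process_recording
    from astroca.scenarios import DEFAULT_CROSSTALK, validation_movie

    movie, geom, gt, hill = validation_movie(seed=0)
    res = process_recording(movie, DEFAULT_CROSSTALK, hill)
    return movie, geom, gt, hill, res
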