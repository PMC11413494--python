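import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_profiles():
    from escapekin import default_profiles

    return default_profiles()


@pytest.fixture(scope="session")
def fixture_trials(default_profiles):
    """A moderate synthetic trial table with field-realistic censoring."""
    from escapekin import default_censoring, generate_trials

    return generate_trials(
        default_profiles, n_per_species=40, censoring=default_censoring(), seed=42
    )


@pytest.fixture()
def toy_trials():
    """Ten hand-written trials covering both modes and every censoring flag."""
    rows = [
        # species, id, mass, fps, mode, reaction, takeoff, disp, air, hit, prem, off, poor
        ("DIME", "DIME-0", 40.0, 240, "jump", 20.0, 90.0, 0.40, 0.20, False, False, False, False),
        ("DIME", "DIME-1", 42.0, 240, "jump", None, None, 0.35, 0.18, True, False, False, False),
        ("DIME", "DIME-2", 38.0, 240, "scramble", 25.0, 120.0, None, None, False, False, False, False),
        ("DIME", "DIME-3", 41.0, 240, "jump", None, None, 0.50, 0.22, False, True, False, False),
        ("DIDE", "DIDE-0", 90.0, 250, "jump", 18.0, 80.0, 0.60, 0.25, False, False, False, False),
        ("DIDE", "DIDE-1", 88.0, 250, "jump", 19.0, 75.0, None, None, False, False, True, False),
        ("DIDE", "DIDE-2", 95.0, 250, "jump", None, None, 0.55, 0.24, False, False, False, True),
        ("CHPE", "CHPE-0", 18.0, 240, "jump", 30.0, 60.0, 0.30, 0.17, False, False, False, False),
        ("CHPE", "CHPE-1", 17.0, 240, "scramble", 28.0, 70.0, None, None, False, False, False, False),
        ("NEAL", "NEAL-0", 180.0, 240, "scramble", 19.0, 150.0, None, None, False, False, False, False),
    ]
    cols = [
        "species",
        "individual_id",
        "mass_g",
        "fps",
        "mode",
        "reaction_ms",
        "takeoff_ms",
        "displacement_m",
        "airborne_s",
        "hit_by_cork",
        "premature",
        "offscreen",
        "poor_video",
    ]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("reaction_ms", "takeoff_ms", "displacement_m", "airborne_s"):
        df[c] = df[c].astype(float)
    return df
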