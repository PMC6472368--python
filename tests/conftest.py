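import pytest
from hypothesis import HealthCheck, settings

import deepseep as ds

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Energies exactly as printed in the study's reaction table (kJ per mole of
#: reaction as written): (dG0, dH0, dG at 4 degC / pH 8 / 2 mM bicarbonate).
PRINTED_TABLE2 = {
    "r1": (1089.1, 1069.8, 753.3),
    "r2": (176.3, 98.4, 133.9),
    "r3": (-407.3, 24.9, -653.3),
    "r4": (120.9, 117.4, 12.8),
    "r5": (-846.3, -1091.3, -950.3),
    "r6": (-76.2, 29.4, -230.7),
}


@pytest.fixture(scope="session")
def db() -> ds.SpeciesTable:
    return ds.SpeciesTable.bundled()


@pytest.fixture(scope="session")
def reactions() -> dict[str, ds.Reaction]:
    return {r.id: r for r in ds.bundled_reactions()}


@pytest.fixture(scope="session")
def deep_sea() -> ds.Conditions:
    return ds.Conditions.deep_sea()
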