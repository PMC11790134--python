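import numpy as np
import pytest

from soilcap.core import SoilSample, SoilSurvey, default_references
from soilcap.synthetic import generate_survey


@pytest.fixture(scope="session")
def refs():
    return default_references()


@pytest.fixture(scope="session")
def survey30():
    """Default stratified survey: 30 sites over 5 land uses, fixed seed."""
    return generate_survey(seed=1)


def make_survey(conc_rows, land_uses=None, coords=None):
    """Hand-build a survey from explicit per-site concentration dicts."""
    n = len(conc_rows)
    land_uses = land_uses or ["residential"] * n
    coords = coords if coords is not None else [(100.0 * i, 50.0 * i) for i in range(n)]
    samples = [
        SoilSample(site_id=f"T{i + 1}", x=coords[i][0], y=coords[i][1],
                   land_use=land_uses[i], conc=dict(conc_rows[i]))
        for i in range(n)
    ]
    return SoilSurvey(samples)


@pytest.fixture
def toy_survey():
    """5-site survey with simple round-number concentrations for oracles."""
    base = {"Pb": 50.0, "Cr": 100.0, "Mn": 2000.0, "Cu": 100.0,
            "Zn": 300.0, "Co": 50.0, "Ni": 100.0, "As": 20.0}
    rows = []
    for scale in (0.5, 1.0, 1.5, 2.0, 4.0):
        rows.append({m: v * scale for m, v in base.items()})
    return make_survey(rows)
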