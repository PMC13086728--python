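import pytest
from hypothesis import settings

from qbd import datasets

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

STUDY_CONFIG_TOML = """\
alpha = 0.05
seed = 0

[[factors]]
name = "PLGA"
low = 25.0
high = 75.0
units = "mg"

[[factors]]
name = "PVA"
low = 1.0
high = 2.0
units = "% w/v"

[[factors]]
name = "Vaq"
low = 0.5
high = 1.0
units = "ml"

[models]
EE_pct = "quadratic"
size_nm = "linear"
Q8h_pct = "quadratic"
Q24_ug_cm2 = "linear"

[goals.EE_pct]
direction = "maximize"

[goals.size_nm]
direction = "minimize"

[goals.Q8h_pct]
direction = "maximize"

[goals.Q24_ug_cm2]
direction = "maximize"
"""


@pytest.fixture(scope="session")
def study():
    """The bundled 15-run nanoparticle formulation study."""
    return datasets.load_formulation_study()


@pytest.fixture(scope="session")
def specs():
    return datasets.factor_specs()


@pytest.fixture()
def study_config_path(tmp_path):
    path = tmp_path / "study.toml"
    path.write_text(STUDY_CONFIG_TOML)
    return path
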