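import json
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from emakit import example_study_path, load_study, loads_study


@pytest.fixture()
def example_study():
    return load_study(example_study_path())


def make_study(modules, calc_variables=None, study_code="TEST1"):
    """Build a single-intervention study from module dicts."""
    doc = {
        "schema_version": 1,
        "study_code": study_code,
        "interventions": [{
            "id": "iv",
            "modules": modules,
            "calc_variables": calc_variables or [],
        }],
    }
    return loads_study(json.dumps(doc))


def slider_module(mid, variable, opening=None, closing=None, notifications=None):
    return {
        "id": mid,
        "items": [{"id": f"{mid}_q", "item_type": "slider",
                   "variable": variable}],
        "opening_rules": opening or [
            {"rule": "relative_to_intervention_start", "offset_minutes": 0}],
        "closing_rules": closing or [],
        "notifications": notifications or [],
    }


@pytest.fixture()
def one_module_study():
    return make_study([slider_module("m1", "mood")])
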