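import pytest

from malpip import load_kb


@pytest.fixture(scope="session")
def kb():
    return load_kb()


CATEGORY_ORDER = {"INDEPENDENT_PIM": 0, "DISEASE_PIM": 1, "PPO": 2}


def sort_findings(findings):
    return sorted(findings, key=lambda f: (f.patient_id, CATEGORY_ORDER[f.category], f.criterion_id))
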