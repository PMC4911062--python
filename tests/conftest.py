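import pytest

from samplearn.language import build_language
from samplearn.pipeline import model_cell_predictions


@pytest.fixture(scope="session")
def exp1():
    return build_language("exp1")


@pytest.fixture(scope="session")
def exp2():
    return build_language("exp2")


@pytest.fixture(scope="session")
def exp3():
    return build_language("exp3")


@pytest.fixture(scope="session")
def specs(exp1, exp2, exp3):
    return {"exp1": exp1, "exp2": exp2, "exp3": exp3}


@pytest.fixture(scope="session")
def predictions(specs):
    """Both learners fitted on each fixture's corpus; per-cell predictions."""
    out = {}
    for name, spec in specs.items():
        strong_post, weak_post, cell_probs = model_cell_predictions(spec, seed=0)
        out[name] = {
            "strong_post": strong_post,
            "weak_post": weak_post,
            "probs": cell_probs,
        }
    return out
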