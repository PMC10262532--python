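import random

import pytest

from kinlaw.classifier import ClassificationResult, RType
from kinlaw.examples import expression_templates, worked_examples


@pytest.fixture(scope="session")
def examples():
    return worked_examples()


@pytest.fixture(scope="session")
def templates():
    return expression_templates()


@pytest.fixture
def rng():
    return random.Random(12345)


def make_result(
    model_id: str, k_type: str, r_label: str = "R=1,P=1", reaction_id: str = "r"
) -> ClassificationResult:
    rb, pb = (part.split("=")[1] for part in r_label.split(","))
    return ClassificationResult(
        model_id=model_id,
        reaction_id=reaction_id,
        reaction="A -> B",
        kinetic_law="k*A",
        k_type=k_type,
        r_type=RType(rb, pb),
    )
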