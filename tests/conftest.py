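import pytest

from cmbayes.confusion import ConfusionMatrix2


@pytest.fixture
def cm_always_dominant() -> ConfusionMatrix2:
    """Classifier that always predicts the dominant class."""
    return ConfusionMatrix2.from_rows([[90, 0], [10, 0]])


@pytest.fixture
def cm_errors_in_dominant() -> ConfusionMatrix2:
    """Discriminating classifier with errors only in the dominant class."""
    return ConfusionMatrix2.from_rows([[80, 10], [0, 10]])


@pytest.fixture
def cm_perfect() -> ConfusionMatrix2:
    return ConfusionMatrix2.from_rows([[90, 0], [0, 10]])


@pytest.fixture
def cm_random() -> ConfusionMatrix2:
    """Uniformly random prediction on 90 + 10 examples."""
    return ConfusionMatrix2.from_rows([[45, 45], [5, 5]])


@pytest.fixture
def cm_errors_fifth() -> ConfusionMatrix2:
    """The errors-in-dominant case with one fifth of the examples."""
    return ConfusionMatrix2.from_rows([[16, 2], [0, 2]])
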