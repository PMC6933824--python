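import math

import pytest

from trophomito import annotate_mitochondrial, datasets, run_differential
from trophomito.types import Stage


@pytest.fixture(scope="session")
def count_records():
    return datasets.load_count_table()


@pytest.fixture(scope="session")
def annotation():
    return datasets.load_annotation()


@pytest.fixture(scope="session")
def annotated(count_records, annotation):
    return annotate_mitochondrial(count_records, annotation)


@pytest.fixture(scope="session")
def differential_results(annotated):
    """Default-config differential results on the 29-protein table."""
    return run_differential(annotated)


@pytest.fixture(scope="session")
def expression_records():
    return [
        record
        for stage in (Stage.FIRST_TRIMESTER, Stage.THIRD_TRIMESTER)
        for record in datasets.load_expression_table(stage)
    ]


def printed_tolerance(text: str, floor: float = 1e-5) -> float:
    """Comparison tolerance for a published numeric string: half a unit in
    the last printed decimal place, but never tighter than ``floor``."""
    if "." in text:
        decimals = len(text.split(".")[1])
        return max(floor, 0.5 * 10.0 ** (-decimals))
    return floor


def assert_matches_printed(computed: float, text: str, floor: float = 1e-5) -> None:
    tolerance = printed_tolerance(text, floor)
    assert math.isfinite(computed)
    assert abs(computed - float(text)) <= tolerance, (
        f"computed {computed!r} vs published {text} (tolerance {tolerance})"
    )
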