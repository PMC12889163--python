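import pytest

from ecbench.ec_core import parse_ec
from ecbench.io_formats import AnnotationTable, PredictionTable


def annot(mapping):
    """Build an AnnotationTable from {pid: [ec strings]}."""
    return AnnotationTable(
        {pid: frozenset(parse_ec(e) for e in ecs) for pid, ecs in mapping.items()}
    )


def preds(name, mapping):
    """Build a PredictionTable from {pid: [(ec string, score), ...]}."""
    return PredictionTable(
        model_name=name,
        entries={
            pid: [(parse_ec(e) if isinstance(e, str) else e, s) for e, s in pairs]
            for pid, pairs in mapping.items()
        },
    )


@pytest.fixture
def simple_truth():
    return annot({"P1": ["1.1.1.1"], "P2": ["2.3.1.4"]})
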