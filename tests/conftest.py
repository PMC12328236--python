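import numpy as np
import pytest

from linpert.data_model import PseudobulkMatrix, parse_condition_label


def make_pb(columns: dict[str, list[float]], gene_ids: list[str] | None = None):
    """Build a PseudobulkMatrix from {label string: per-gene values}."""
    labels = [parse_condition_label(s) for s in columns]
    values = np.column_stack([np.asarray(v, dtype=float) for v in columns.values()])
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    control_index = next(i for i, lab in enumerate(labels) if lab.is_control)
    return PseudobulkMatrix(values, gene_ids, labels, control_index)


@pytest.fixture
def simple_pb():
    """4 genes x {ctrl, A+ctrl, B+ctrl, A+B}; targets named after genes."""
    return make_pb(
        {
            "ctrl": [1.0, 2.0, 3.0, 4.0],
            "g0+ctrl": [2.0, 2.0, 3.5, 4.0],
            "g1+ctrl": [1.0, 3.0, 3.0, 5.0],
            "g0+g1": [2.5, 3.5, 3.5, 5.5],
        }
    )
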