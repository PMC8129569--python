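import numpy as np
import pandas as pd
import pytest

from lplpipe.matrix import ExpressionMatrix


def make_matrix(values, classes, species="mouse", gene_prefix="g"):
    """Small ExpressionMatrix from a 2-D array and a list of class labels."""
    values = np.asarray(values, dtype=float)
    counts: dict[str, int] = {}
    cols = []
    for lab in classes:
        counts[lab] = counts.get(lab, 0) + 1
        cols.append(f"{lab}_{counts[lab]}")
    df = pd.DataFrame(
        values,
        index=[f"{gene_prefix}{i + 1}" for i in range(values.shape[0])],
        columns=cols,
    )
    return ExpressionMatrix(df, species, {c: c.rsplit("_", 1)[0] for c in cols})


@pytest.fixture
def two_group_matrix():
    """One gene with a clean 1.5 log2 shift, one flat gene."""
    return make_matrix(
        [[5.0, 5.0, 5.0, 6.5, 6.5, 6.5], [7.0, 7.0, 7.0, 7.0, 7.0, 7.0]],
        ["A", "A", "A", "B", "B", "B"],
    )
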