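from __future__ import annotations

import pandas as pd
import pytest

from lincseek.express import ExpressionMatrix
from lincseek.synthio import SynthConfig, SynthDataset, generate_dataset


def make_expr(ds: SynthDataset) -> ExpressionMatrix:
    """ExpressionMatrix over all synthetic transcripts (assembled + reference)."""
    lengths = pd.Series(
        {t.transcript_id: t.length for t in ds.assembled}
        | {t.transcript_id: t.length for t in ds.reference}
    )
    return ExpressionMatrix(ds.counts, ds.design, lengths, ds.totals)


@pytest.fixture(scope="session")
def ds() -> SynthDataset:
    """Default-scale synthetic dataset with planted truth."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def ds_big() -> SynthDataset:
    """Larger dataset for statistical recovery checks."""
    cfg = SynthConfig(
        seed=11,
        n_coding_genes=120,
        n_linc=120,
        n_intronic=40,
        n_antisense=30,
        n_trans_pairs=20,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def ds_files(tmp_path_factory) -> SynthDataset:
    """Dataset written to disk (for I/O, CLI and end-to-end tests)."""
    out = tmp_path_factory.mktemp("synthds")
    return generate_dataset(SynthConfig(seed=7), out)


@pytest.fixture(scope="session")
def expr(ds):
    return make_expr(ds)
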