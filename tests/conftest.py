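import numpy as np
import pandas as pd
import pytest

from trnatlas import ExpressionMatrix, IsodecoderRecord


def make_record(isotype, anticodon, copy=1, compartment="cytosolic", seq=""):
    name = f"{isotype}-{anticodon}-{copy}-1"
    return IsodecoderRecord(
        id=name,
        member_names=[name],
        sequence=seq or f"SEQ-{name}",
        isotype=isotype,
        anticodon=anticodon,
        compartment=compartment,
    )


@pytest.fixture
def toy_records():
    """6 cytosolic isodecoders: 2 Gly anticodons, 1 Ala, 1 Leu."""
    return [
        make_record("Gly", "GCC", 1),
        make_record("Gly", "GCC", 2),
        make_record("Gly", "CCC", 1),
        make_record("Ala", "AGC", 1),
        make_record("Ala", "AGC", 2),
        make_record("Leu", "AAG", 1),
    ]


@pytest.fixture
def toy_matrix(toy_records):
    """Deterministic positive RPM values, 4 samples over 2 tissues."""
    rng = np.random.default_rng(42)
    ids = [r.id for r in toy_records]
    samples = ["t1_rep1", "t1_rep2", "t2_rep1", "t2_rep2"]
    vals = pd.DataFrame(
        rng.uniform(10, 1000, (len(ids), len(samples))), index=ids, columns=samples
    )
    tissue = pd.Series({s: s.split("_")[0] for s in samples})
    return ExpressionMatrix(vals, tissue, level="isodecoder", unit="rpm")


@pytest.fixture
def rng():
    return np.random.default_rng(7)
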