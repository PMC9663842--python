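import numpy as np
import pandas as pd
import pytest

from perifat.genomic import GeneModel, GenomicInterval
from perifat.io import ExpressionCountMatrix, MethylationCallTable, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def sexes12():
    samples = [f"M{i}" for i in range(1, 7)] + [f"F{i}" for i in range(1, 7)]
    return pd.Series(["M"] * 6 + ["F"] * 6, index=samples)


@pytest.fixture
def metadata12(sexes12, rng):
    frame = pd.DataFrame(index=pd.Index(sexes12.index, name="sample_id"))
    frame["sex"] = sexes12
    frame["age_days"] = 26.0
    for t in ("renal", "pelvic", "renal_and_pelvic", "leg_intramuscular",
              "leg_subcutaneous"):
        frame[t] = np.round(rng.uniform(5, 30, size=len(frame)), 2)
    return SampleTable(frame)


def make_counts(matrix, lengths=None, samples=None, genes=None):
    """Build an ExpressionCountMatrix from a plain array."""
    matrix = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    lengths = lengths if lengths is not None else [1000.0] * matrix.shape[0]
    return ExpressionCountMatrix(
        pd.DataFrame(matrix, index=genes, columns=samples),
        pd.Series(lengths, index=genes, dtype=float),
    )


def make_calls(rows, samples):
    """Build a MethylationCallTable from (chrom, pos, context, {s: (m, n)})."""
    recs = []
    for chrom, pos, context, per_sample in rows:
        rec = dict(chrom=chrom, pos=pos, strand="+", context=context)
        for s in samples:
            m, n = per_sample[s]
            rec[f"{s}_meth"] = m
            rec[f"{s}_total"] = n
        recs.append(rec)
    cols = ["chrom", "pos", "strand", "context"] + [
        c for s in samples for c in (f"{s}_meth", f"{s}_total")
    ]
    return MethylationCallTable(pd.DataFrame(recs, columns=cols), list(samples))


@pytest.fixture
def toy_gene():
    return GeneModel(
        "G1",
        GenomicInterval("1", 100, 200, "+"),
        [GenomicInterval("1", 100, 140, "+"), GenomicInterval("1", 160, 200, "+")],
    )
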