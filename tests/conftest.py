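import numpy as np
import pandas as pd
import pytest

from batmuscle import CountMatrix, compute_cpm, log2_transform


@pytest.fixture
def toy_counts_files(tmp_path):
    """3-gene x 2-sample counts TSV plus design TSV on disk."""
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "gene\ts1\ts2\n"
        "Actb\t10\t20\n"
        "Gusb\t90\t60\n"
        "Myh1\t0\t20\n"
    )
    design = tmp_path / "design.tsv"
    design.write_text(
        "sample\ttimepoint\treplicate\n"
        "s1\tT0\t1\n"
        "s2\tT30\t1\n"
    )
    return counts, design


def make_count_matrix(counts: dict, design: dict) -> CountMatrix:
    """counts: gene -> list per sample; design: sample -> timepoint."""
    samples = list(design)
    cdf = pd.DataFrame(counts, index=samples).T.astype(np.int64)
    ddf = pd.DataFrame({"timepoint": [design[s] for s in samples],
                        "replicate": list(range(1, len(samples) + 1))},
                       index=pd.Index(samples, name="sample"))
    return CountMatrix(counts=cdf, design=ddf)


@pytest.fixture
def five_gene_matrix():
    """5 genes, 2 baseline + 2 stimulated samples, hand-enterable counts."""
    return make_count_matrix(
        {
            "Actb": [100, 200, 150, 300],
            "Gusb": [50, 100, 75, 150],
            "Tbp": [25, 50, 40, 80],
            "CandA": [10, 20, 60, 120],
            "CandB": [40, 80, 30, 60],
        },
        {"s1": "T0", "s2": "T0", "s3": "T30", "s4": "T30"},
    )


@pytest.fixture
def five_gene_log2(five_gene_matrix):
    return log2_transform(compute_cpm(five_gene_matrix), pseudocount=1.0)
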