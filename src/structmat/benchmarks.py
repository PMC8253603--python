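"""Published benchmark summaries bundled with the package.

``dr1_benchmark_summary`` ships the per-structure ensemble averages (mean ±
SD of peptide-core contacts and main-chain hydrogen bonds, from molecular
dynamics and backrub Monte Carlo sampling) for ten DRB1*01:01 crystal
complexes.  It is input data for the grand-average summarization, not a
computed result of this package.
"""

from importlib import resources

import pandas as pd


def dr1_benchmark_summary() -> pd.DataFrame:
    """Per-structure observable means for the 10-complex DR1 benchmark set."""
    with resources.files("structmat.data").joinpath(
            "dr1_benchmark_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
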