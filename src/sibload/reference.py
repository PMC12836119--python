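"""Published logistic-load estimates for the 11 assayed Caenorhabditis strains.

These per-strain (beta0, beta1) coefficients and standard errors come from
the serial sib-mating extinction experiment (10 wild gonochoristic isolates
plus the fully inbred C. elegans fog-2 control).  They are shipped as
reference inputs: the load parameters A_R and B_R and the Wald test for
concealed load are always recomputed from the coefficients, never stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["strain_estimates"]


def strain_estimates() -> pd.DataFrame:
    """Reference coefficient table, one row per strain.

    Columns: species, strain, locality, beta0, se0, beta1, se1.
    """
    with resources.files("sibload.data").joinpath("strain_estimates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
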