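"""Packaged worked-example data.

The shipped table carries the published normalized 2DE spot quantities for
the 69 proteins reported predominant in *Ciona intestinalis* branchial cilia
(18) or sperm flagella (51), with the printed flagella/cilia ratio. It is the
ground truth the classifier's worked examples are checked against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_predominant_spots"]


def load_predominant_spots() -> pd.DataFrame:
    """The published predominant-protein quantity table.

    Columns: ``predominant_in`` ("cilia"/"flagella" — which table the row was
    printed in), ``category``, ``q_flagella``, ``q_cilia`` (normalized spot
    quantities), ``fc_printed`` (printed flagella/cilia ratio, "-" when one
    side was not detected) and ``protein``.
    """
    path = resources.files("axoprot") / "data" / "ciona_predominant_spots.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"fc_printed": str})
    df["q_flagella"] = df["q_flagella"].astype(float)
    df["q_cilia"] = df["q_cilia"].astype(float)
    return df
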