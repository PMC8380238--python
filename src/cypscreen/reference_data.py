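"""Bundled reference tables.

``load_measured_test_compounds`` returns the published inhibition
measurements for the 22 validation compounds assayed against recombinant
CYP1A1: IC50 (µM, with "> 200" censoring at the top tested concentration
and "inf" for compounds best fitted by the constant model) and, for the 13
compounds with IC50 < 100 µM, K_i, α and their 95% CIs plus the assigned
mode of inhibition.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_measured_test_compounds() -> pd.DataFrame:
    with resources.files("cypscreen.data").joinpath(
        "cyp1a1_test_compound_kinetics.csv"
    ).open() as fh:
        return pd.read_csv(fh)
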