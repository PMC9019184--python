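"""Bundled reference data."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_bendamustine_panel"]


def load_bendamustine_panel() -> pd.DataFrame:
    """Published bendamustine screen summaries for 25 B-cell cancer cell lines.

    One row per cell line (14 DLBCL, 11 MM) with doubling time T0 (hours),
    GI50 / TGI / LC48 in log10(µg/mL), AUC0 (percent·log10-dose units) and the
    parametric-bootstrap 95% CI bounds of each (``*_lo``, ``*_hi``), from a
    16-dose two-fold bendamustine ladder topping out at 500 µg/mL.
    """
    with resources.files("regskit.data").joinpath("bendamustine_panel.csv").open() as fh:
        return pd.read_csv(fh)
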