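"""Readers and writers for the plain-text interchange formats.

* expression TSV: first column ``feature_id``, remaining columns sample ids,
  log-scale float values;
* survival CSV: ``sample_id, time, event`` (event 1 = observed death);
* plate CSV: schema documented in :mod:`regskit.dose_response`.
"""

from __future__ import annotations

import pandas as pd


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "feature_id":
        raise ValueError("expression TSV must start with a 'feature_id' column")
    df = df.set_index("feature_id")
    if df.index.has_duplicates:
        raise ValueError("feature ids must be unique")
    return df.astype(float)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival CSV missing column {col!r}")
    return df


def write_survival_csv(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, index=False)
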