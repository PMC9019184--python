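import numpy as np
import pandas as pd
import pytest

from regskit import (
    CellLineTruth,
    DoseLadder,
    SignatureModel,
    assign_tertiles,
    simulate_expression,
    simulate_panel,
    simulate_plate,
)
from regskit.dose_response import screen_to_table
from regskit.signature import SignatureResults


@pytest.fixture(scope="session")
def ladder():
    return DoseLadder()  # 16 two-fold dilutions from 500 µg/mL


@pytest.fixture(scope="session")
def truth():
    return CellLineTruth(
        name="TEST",
        disease="DLBCL",
        doubling_time_h=30.0,
        gi50_log10=1.5,
        hill_slope=3.0,
        floor_growth=-0.8,
        seeding_signal=0.2,
    )


@pytest.fixture(scope="session")
def noiseless_plate(truth):
    return simulate_plate(truth, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_plate(truth):
    return simulate_plate(truth, noise_sd=0.01, seed=1)


@pytest.fixture(scope="session")
def small_panel():
    """A (14, 11)-line panel with summary table and tertile labels, no bootstrap."""
    plates, truths = simulate_panel(14, 11, seed=42)
    table = screen_to_table(plates, B=0)
    table["disease"] = [t.disease for t in truths]
    labels = assign_tertiles(table)
    return plates, truths, table, labels


@pytest.fixture(scope="session")
def trained_signature(small_panel):
    """A signature trained on a small planted-gene expression matrix."""
    _, truths, _, labels = small_panel
    lab_map = {l.cell_line: l.tertile for l in labels}
    expr = simulate_expression(
        truths, lab_map, n_genes=200, n_signature=8, effect_size=3.0, seed=11
    )
    labels_df = pd.DataFrame([l.__dict__ for l in labels])
    results = SignatureModel(expr, labels_df).fit()
    return expr, labels_df, results


@pytest.fixture()
def toy_signature():
    """A hand-built three-gene signature for prediction/cohort tests."""
    p = 40
    fids = [f"G{i:03d}" for i in range(p)]
    coef = np.zeros(p)
    coef[:3] = [1.5, -1.0, 0.8]
    return SignatureResults(
        feature_ids=fids,
        center=np.full(p, 7.0),
        scale=np.ones(p),
        intercept=-0.2,
        coefficients=coef,
        mixing_a=0.5,
        penalty_lambda=0.1,
        cv_error=0.2,
    )
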