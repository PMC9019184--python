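"""Synthetic data generators for the full resistance-signature pipeline.

Every downstream stage (dose-response summarisation, drug correlation,
signature training, cohort stratification) can be exercised against data with
known ground truth:

* plates — exponential cell growth with a 4PL dose-dependent inhibition of the
  growth rate, additive Gaussian plate-reader noise truncated at zero, border
  wells with an evaporation bias, vehicle controls in one interior column;
* cell-line panels — DLBCL/MM-like panels with per-line doubling time, GI50,
  Hill slope and growth floor drawn from ranges matching published screens;
* expression matrices — a shared Gaussian baseline with a planted subset of
  genes shifted between resistant and sensitive lines;
* patient cohorts — expression drawn so that a given signature model produces
  subtype-specific resistance-probability shifts, plus proportional-hazards
  exponential survival with independent censoring.

The plate generator uses the same exponential/4PL growth model the fitter
assumes, so noiseless plates are recovered exactly; an optional lag-phase term
(``lag_h``) mis-specifies the model on purpose for robustness tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseLadder, PlateAssay, four_pl

__all__ = [
    "CellLineTruth",
    "CohortTruth",
    "simulate_plate",
    "simulate_panel",
    "simulate_expression",
    "simulate_cohort",
]

LN2 = math.log(2.0)

# default 96-well geometry; controls occupy one interior column
N_ROWS, N_COLS = 8, 12
CONTROL_COL = 10
DOSE_COLS = range(2, 10)  # 8 columns x 6 interior rows = 48 dose wells
INTERIOR_ROWS = range(2, 8)
BORDER_GROWTH_BIAS = 1.10  # evaporation makes border wells grow ~10% faster


@dataclass(frozen=True)
class CellLineTruth:
    """Ground-truth growth and dose-response parameters for one cell line.

    ``gi50_log10`` is the log10 dose (µg/mL) at which relative growth crosses
    0.5; ``floor_growth`` is the high-dose plateau of relative growth (may be
    negative: net cell death); ``seeding_signal`` is the absorbance of the
    seeded wells at the 0 h read.
    """

    name: str
    disease: str  # {"DLBCL", "MM"}
    doubling_time_h: float
    gi50_log10: float
    hill_slope: float
    floor_growth: float
    seeding_signal: float

    def __post_init__(self) -> None:
        if not 10 <= self.doubling_time_h <= 200:
            raise ValueError("doubling_time_h must be in [10, 200]")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")
        if not -3 <= self.floor_growth < 1:
            raise ValueError("floor_growth must be in [-3, 1)")
        if self.seeding_signal <= 0:
            raise ValueError("seeding_signal must be positive")
        if self.disease not in ("DLBCL", "MM"):
            raise ValueError("disease must be DLBCL or MM")

    @property
    def midpoint_log10(self) -> float:
        """4PL midpoint consistent with gi50_log10 (upper fixed at 1)."""
        if self.floor_growth < 0.5:
            return self.gi50_log10 - math.log(0.5 / (0.5 - self.floor_growth)) / self.hill_slope
        # floor above 0.5: relative growth never crosses 0.5; interpret the
        # stated value as the curve midpoint directly
        return self.gi50_log10

    def relative_growth(self, log10_dose):
        """True relative growth G(d) at log10 dose, 4PL with upper = 1."""
        return four_pl(log10_dose, 1.0, self.floor_growth, self.hill_slope, self.midpoint_log10)

    def rate_per_h(self, dose_ug_ml: float) -> float:
        """Growth rate at a dose: G(d) · ln2 / doubling time; control rate at d = 0."""
        if dose_ug_ml <= 0:
            g = 1.0
        else:
            g = float(self.relative_growth(math.log10(dose_ug_ml)))
        return g * LN2 / self.doubling_time_h


def _plate_layout(ladder: DoseLadder) -> list[tuple[int, int, float, int]]:
    """(row, col, dose, is_border) for every laid-out well of one plate."""
    doses = ladder.doses
    wells = []
    # interior dose wells: 16 doses x 3 wells, column-major over rows 2-7, cols 2-9
    idx = 0
    for col in DOSE_COLS:
        for row in INTERIOR_ROWS:
            wells.append((row, col, float(doses[idx % ladder.n_doses]), 0))
            idx += 1
    # interior control column
    for row in INTERIOR_ROWS:
        wells.append((row, CONTROL_COL, 0.0, 0))
    # border wells: cycle control + ladder so the exclusion rule is testable
    border_cycle = [0.0] + [float(d) for d in doses]
    k = 0
    for row in range(1, N_ROWS + 1):
        for col in range(1, N_COLS + 1):
            if row in (1, N_ROWS) or col in (1, N_COLS):
                wells.append((row, col, border_cycle[k % len(border_cycle)], 1))
                k += 1
    return wells


def simulate_plate(
    truth: CellLineTruth,
    ladder: DoseLadder | None = None,
    noise_sd: float = 0.01,
    seed: int | None = None,
    n_replicates: int = 3,
    drug: str = "bendamustine",
    lag_h: float = 0.0,
) -> PlateAssay:
    """Simulate a two-timepoint viability screen for one cell line.

    Each replicate experiment contributes a 0 h and a 48 h plate; the signal of
    a well at dose d and time t is ``seeding_signal · exp(rate(d)·t)`` plus
    Gaussian noise truncated at zero, with ``rate(d) = G(d)·ln2/T0``.  Border
    wells grow 10% faster (evaporation) and are flagged ``is_border = 1``.
    ``lag_h`` delays growth by a lag phase, deliberately violating the fitted
    model (robustness testing only).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ladder = ladder if ladder is not None else DoseLadder()
    rng = np.random.default_rng(seed)
    layout = _plate_layout(ladder)
    records = []
    for rep in range(1, n_replicates + 1):
        for t in (0.0, 48.0):
            t_eff = max(t - lag_h, 0.0)
            for row, col, dose, is_border in layout:
                rate = truth.rate_per_h(dose)
                if is_border:
                    rate *= BORDER_GROWTH_BIAS
                signal = truth.seeding_signal * math.exp(rate * t_eff)
                if noise_sd > 0:
                    signal = max(signal + rng.normal(0.0, noise_sd), 0.0)
                records.append(
                    {
                        "cell_line": truth.name,
                        "drug": drug,
                        "replicate": rep,
                        "row": row,
                        "col": col,
                        "dose_ug_ml": dose,
                        "timepoint_h": t,
                        "absorbance": signal,
                        "is_border": is_border,
                    }
                )
    return PlateAssay(pd.DataFrame.from_records(records))


# truth-parameter ranges for panel simulation, matching the spread seen in
# published DLBCL/MM bendamustine screens (T0 ~ 23-70 h for most lines, GI50
# 0.44-2.10 log10 µg/mL, clear high-dose cell decay)
PANEL_RANGES = {
    "doubling_time_h": (24.0, 70.0),
    "gi50_log10": (0.5, 2.05),
    "hill_slope": (1.5, 5.0),
    "floor_growth": (-1.2, -0.3),
    "seeding_signal": (0.15, 0.35),
}


def simulate_panel(
    n_dlbcl: int,
    n_mm: int,
    seed: int | None = None,
    ladder: DoseLadder | None = None,
    noise_sd: float = 0.01,
    ranges: dict | None = None,
) -> tuple[list[PlateAssay], list[CellLineTruth]]:
    """Simulate a cell-line panel: one plate assay + ground truth per line."""
    if n_dlbcl < 3 or n_mm < 3:
        raise ValueError("need >=3 cell lines per disease (tertiles undefined otherwise)")
    ranges = dict(PANEL_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    truths = []
    for disease, n in (("DLBCL", n_dlbcl), ("MM", n_mm)):
        for i in range(n):
            params = {k: float(rng.uniform(*ranges[k])) for k in PANEL_RANGES}
            truths.append(CellLineTruth(name=f"{disease}-{i + 1:02d}", disease=disease, **params))
    plate_seeds = rng.integers(0, 2**31, size=len(truths))
    plates = [
        simulate_plate(t, ladder=ladder, noise_sd=noise_sd, seed=int(s))
        for t, s in zip(truths, plate_seeds)
    ]
    return plates, truths


def simulate_expression(
    truths: list[CellLineTruth],
    labels: dict,
    n_genes: int = 2000,
    n_signature: int = 10,
    effect_size: float = 3.0,
    seed: int | None = None,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate a log2 expression matrix (features × samples) with planted genes.

    Non-signature genes share a Gaussian baseline; each planted gene is shifted
    by ``+effect_size`` in one class and ``-effect_size`` in the other (random
    sign per gene), with intermediate lines at the midpoint.  Planted genes are
    identifiable by their ``SIG####`` feature ids; the rest are ``G####``.
    """
    if n_signature > n_genes:
        raise ValueError("n_signature must be <= n_genes")
    classes = {labels[t.name] for t in truths if t.name in labels}
    if not {"sensitive", "resistant"} <= classes:
        raise ValueError("labels must contain both sensitive and resistant lines")
    rng = np.random.default_rng(seed)
    samples = [t.name for t in truths]
    feature_ids = [f"SIG{i + 1:04d}" for i in range(n_signature)] + [
        f"G{i + 1:04d}" for i in range(n_genes - n_signature)
    ]
    mu = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, len(samples)))
    signs = rng.choice([-1.0, 1.0], size=n_signature)
    direction = {"resistant": 1.0, "sensitive": -1.0, "intermediate": 0.0}
    for j, name in enumerate(samples):
        d = direction.get(labels.get(name, "intermediate"), 0.0)
        values[:n_signature, j] += signs * effect_size * d
    return pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"), columns=samples)


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth for a simulated patient cohort.

    ``subtype_resistance_shift`` moves each subtype's signature score on the
    logit scale, so subtype means of the predicted resistance probability are
    ordered like the shifts.  ``hazard_coef`` is the log-hazard increase per
    unit of resistance probability; censoring is independent of survival.
    """

    n_patients: int
    subtypes: tuple = ("naive", "centrocyte", "centroblast", "memory", "plasmablast")
    subtype_shares: tuple = (0.15, 0.35, 0.2, 0.2, 0.1)
    subtype_resistance_shift: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    hazard_coef: float = 0.0
    censor_fraction: float = 0.2
    median_survival_months: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subtypes) == 0:
            raise ValueError("subtype list must be non-empty")
        if len(self.subtypes) != len(self.subtype_shares) or len(self.subtypes) != len(
            self.subtype_resistance_shift
        ):
            raise ValueError("subtypes, shares and shifts must have equal length")
        if abs(sum(self.subtype_shares) - 1.0) > 1e-8:
            raise ValueError("subtype shares must sum to 1")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


def simulate_cohort(model, truth: CohortTruth):
    """Simulate a patient cohort coupled to a fitted signature model.

    Returns ``(expression, class_probabilities, survival)``:

    * expression (features × samples) drawn so that the model's predicted
      resistance probability carries the subtype-specific logit shifts;
    * a subtype class-probability matrix (samples × subtypes, rows sum to 1)
      concentrated on each sample's true subtype;
    * a survival table with exponential times whose hazard is proportional to
      ``exp(hazard_coef · resistance probability)`` and independent censoring:
      each sample is censored with probability ``censor_fraction`` at a time
      uniform on (0, T).

    ``model`` is a fitted signature results object exposing ``feature_ids``,
    ``center``, ``scale``, ``intercept`` and ``coefficients``.
    """
    coef = np.asarray(model.coefficients, float)
    if not np.any(coef != 0):
        raise ValueError("signature model must have at least one nonzero coefficient")
    rng = np.random.default_rng(truth.seed)
    n, p = truth.n_patients, len(model.feature_ids)
    labels = rng.choice(len(truth.subtypes), size=n, p=np.asarray(truth.subtype_shares))
    shifts = np.asarray(truth.subtype_resistance_shift, float)[labels]

    z = rng.normal(0.0, 1.0, size=(p, n))
    # move each sample along the coefficient direction by its subtype shift,
    # which adds exactly `shift` to the linear predictor
    z += np.outer(coef / float(coef @ coef), shifts)
    center = np.asarray(model.center, float)[:, None]
    scale = np.asarray(model.scale, float)[:, None]
    expr = pd.DataFrame(
        center + scale * z,
        index=pd.Index(list(model.feature_ids), name="feature_id"),
        columns=[f"P{i + 1:04d}" for i in range(n)],
    )

    eta = model.intercept + coef @ z
    prob = 1.0 / (1.0 + np.exp(-eta))

    conc = np.ones((n, len(truth.subtypes)))
    conc[np.arange(n), labels] += 7.0
    class_prob = np.vstack([rng.dirichlet(c) for c in conc])
    class_prob_df = pd.DataFrame(class_prob, index=expr.columns, columns=list(truth.subtypes))
    class_prob_df.index.name = "sample_id"

    base_hazard = LN2 / truth.median_survival_months
    hazard = base_hazard * np.exp(truth.hazard_coef * prob)
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < truth.censor_fraction
    obs_times = np.where(censored, rng.uniform(0.0, times), times)
    surv = pd.DataFrame(
        {
            "sample_id": expr.columns,
            "time": np.maximum(obs_times, 1e-6),
            "event": (~censored).astype(int),
            "subtype": [truth.subtypes[k] for k in labels],
        }
    )
    return expr, class_prob_df, surv
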