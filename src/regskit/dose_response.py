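"""Growth-rate-corrected dose-response analysis for two-timepoint viability screens.

A screen reads one 96-well plate immediately after drug addition (0 h) and a
sister plate after 48 h of exposure, over a geometric dose ladder plus vehicle
controls.  Under exponential growth the per-dose growth rate is
``ln(A48/A0)/dt`` and dividing by the control rate gives the *relative growth*
``g``: 1 means the drug had no effect, 0 means stasis, negative values mean net
cell death.  Because ``g`` is a ratio of rates it is independent of assay
duration and of how fast the untreated line grows, which removes the bias that
makes fast-growing lines look drug-sensitive at a fixed endpoint.

A four-parameter logistic (4PL) in log10 dose is fitted to the ``g`` values and
summarised by:

* ``T0``   — doubling time of the untreated line (hours),
* ``GI50`` — log10 dose giving 50% growth inhibition (g = 0.5),
* ``TGI``  — log10 dose of total growth inhibition (g = 0),
* ``LC48`` — log10 dose at which the population halves over 48 h (g = -T0/48),
* ``AUC0`` — area under the positive part of 100·g over the tested log10-dose
  range (percent·log10-dose units); the primary resistance summary.

Confidence intervals come from a parametric bootstrap around the fitted curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseLadder",
    "PlateAssay",
    "GrowthParams",
    "DoseResponseCurve",
    "SummaryStats",
    "DoseResponseModel",
    "DoseResponseResults",
    "four_pl",
    "estimate_growth",
    "relative_growth",
    "fit_curve",
    "summarize",
    "bootstrap_cis",
    "screen_to_table",
    "read_plates_csv",
]

PLATE_COLUMNS = [
    "cell_line",
    "drug",
    "replicate",
    "row",
    "col",
    "dose_ug_ml",
    "timepoint_h",
    "absorbance",
    "is_border",
]


class FitError(RuntimeError):
    """Raised when the dose-response curve cannot be fitted."""


@dataclass(frozen=True)
class DoseLadder:
    """Geometric dose ladder: ``top_dose / fold**k`` for k = 0..n_doses-1."""

    top_dose: float = 500.0
    n_doses: int = 16
    fold: float = 2.0

    def __post_init__(self) -> None:
        if self.top_dose <= 0:
            raise ValueError("top_dose must be positive")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.n_doses < 2:
            raise ValueError("need at least 2 doses")

    @property
    def doses(self) -> np.ndarray:
        """Doses in µg/mL, strictly decreasing."""
        return self.top_dose / self.fold ** np.arange(self.n_doses)

    @property
    def log10_doses(self) -> np.ndarray:
        return np.log10(self.doses)

    @property
    def log10_max(self) -> float:
        return math.log10(self.top_dose)

    @property
    def log10_min(self) -> float:
        return math.log10(self.top_dose) - (self.n_doses - 1) * math.log10(self.fold)

    @property
    def log10_range(self) -> float:
        return (self.n_doses - 1) * math.log10(self.fold)


@dataclass
class PlateAssay:
    """Well-level absorbances for one cell line × drug screen.

    ``data`` holds one row per well per timepoint with the columns in
    :data:`PLATE_COLUMNS`.  Border wells are present but flagged
    (``is_border == 1``) and are excluded from every computation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PLATE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"plate data missing columns: {sorted(missing)}")

    @property
    def cell_line(self) -> str:
        return str(self.data["cell_line"].iloc[0])

    @property
    def drug(self) -> str:
        return str(self.data["drug"].iloc[0])

    @property
    def timepoints(self) -> tuple[float, float]:
        t = np.sort(self.data["timepoint_h"].unique())
        if len(t) != 2:
            raise ValueError(f"expected exactly 2 timepoints, got {list(t)}")
        return float(t[0]), float(t[1])

    def interior(self) -> pd.DataFrame:
        """Non-border wells only."""
        return self.data[self.data["is_border"] == 0]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlateAssay":
        return cls(pd.read_csv(path))


def read_plates_csv(path) -> list[PlateAssay]:
    """Read a plate CSV and split it into one :class:`PlateAssay` per cell line × drug."""
    df = pd.read_csv(path)
    return [
        PlateAssay(sub.reset_index(drop=True))
        for _, sub in df.groupby(["cell_line", "drug"], sort=True)
    ]


@dataclass
class GrowthParams:
    """Control growth rate and doubling time, with bootstrap ingredients.

    ``doubling_time_h`` is NaN and ``defined`` False when the controls did not
    grow (rate <= 0).  The log-absorbance summaries of the control wells are
    kept so that the parametric bootstrap can resample T0.
    """

    rate_per_h: float
    doubling_time_h: float
    defined: bool
    dt_h: float
    log_a0_mean: float
    log_a0_sd: float
    n0: int
    log_a48_mean: float
    log_a48_sd: float
    n48: int
    ci: tuple[float, float] | None = None


def estimate_growth(plate: PlateAssay) -> GrowthParams:
    """Control growth rate r0 = ln(mean A48 / mean A0) / dt and T0 = ln2 / r0.

    Uses the mean absorbance of the non-border control wells at each timepoint;
    the 0 h and 48 h readings come from physically different plates, so wells
    are averaged per timepoint rather than paired.
    """
    t_lo, t_hi = plate.timepoints
    dt = t_hi - t_lo
    interior = plate.interior()
    ctrl = interior[interior["dose_ug_ml"] == 0]
    out = {}
    for t, key in ((t_lo, "0"), (t_hi, "48")):
        a = ctrl.loc[ctrl["timepoint_h"] == t, "absorbance"].to_numpy(float)
        if len(a) < 2:
            raise ValueError(f"need >=2 non-border control wells at t={t} h")
        if a.mean() <= 0:
            raise ValueError(f"non-positive mean control absorbance at t={t} h")
        out[key] = a
    a0, a48 = out["0"], out["48"]
    r0 = math.log(a48.mean() / a0.mean()) / dt
    defined = r0 > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        la0 = np.log(np.maximum(a0, 1e-12))
        la48 = np.log(np.maximum(a48, 1e-12))
    return GrowthParams(
        rate_per_h=r0,
        doubling_time_h=math.log(2) / r0 if defined else float("nan"),
        defined=defined,
        dt_h=dt,
        log_a0_mean=float(la0.mean()),
        log_a0_sd=float(la0.std(ddof=1)),
        n0=len(a0),
        log_a48_mean=float(la48.mean()),
        log_a48_sd=float(la48.std(ddof=1)),
        n48=len(a48),
    )


def relative_growth(plate: PlateAssay, growth: GrowthParams) -> pd.DataFrame:
    """Relative growth g per dose and replicate, from non-border wells.

    For each dose d and replicate, g = [ln(A48_d / A0_d) / dt] / r0 where the
    absorbances are means over that replicate's interior wells at the dose.
    Returns a data frame with columns ``log10_dose, g, replicate``.
    """
    if not growth.defined:
        raise ValueError("control growth rate must be positive")
    t_lo, t_hi = plate.timepoints
    interior = plate.interior()
    treated = interior[interior["dose_ug_ml"] > 0]
    rows = []
    for (dose, rep), sub in treated.groupby(["dose_ug_ml", "replicate"], sort=True):
        a0 = sub.loc[sub["timepoint_h"] == t_lo, "absorbance"].to_numpy(float)
        a48 = sub.loc[sub["timepoint_h"] == t_hi, "absorbance"].to_numpy(float)
        if len(a0) == 0 or len(a48) == 0:
            raise ValueError(f"dose {dose} replicate {rep}: missing a timepoint")
        if a0.mean() <= 0 or a48.mean() <= 0:
            raise ValueError(f"dose {dose} replicate {rep}: non-positive absorbance")
        rate = math.log(a48.mean() / a0.mean()) / growth.dt_h
        rows.append(
            {"log10_dose": math.log10(dose), "g": rate / growth.rate_per_h, "replicate": rep}
        )
    return pd.DataFrame(rows).sort_values(["log10_dose", "replicate"]).reset_index(drop=True)


def four_pl(x, upper, lower, slope, midpoint):
    """Four-parameter logistic in log10 dose, decreasing for slope > 0."""
    x = np.asarray(x, float)
    return lower + (upper - lower) / (1.0 + np.exp(np.clip(slope * (x - midpoint), -500, 500)))


@dataclass
class DoseResponseCurve:
    """Fitted 4PL: g(x) = lower + (upper - lower)/(1 + exp(slope·(x - midpoint)))."""

    upper: float
    lower: float
    slope: float
    midpoint: float
    residual_sd: float
    is_flat: bool = False

    def predict(self, x):
        if self.is_flat:
            x = np.asarray(x, float)
            return np.full_like(x, self.upper, dtype=float)
        return four_pl(x, self.upper, self.lower, self.slope, self.midpoint)

    def solve(self, target: float) -> float:
        """The log10 dose at which the curve crosses ``target``.

        Returns +inf when the curve stays above the target (never attained at
        any finite dose), -inf when it starts below it, NaN for a flat curve.
        """
        if self.is_flat:
            return float("nan")
        if target >= self.upper:
            return float("-inf")
        if target <= self.lower:
            return float("inf")
        return self.midpoint + math.log((self.upper - self.lower) / (target - self.lower) - 1.0) / self.slope


_SLOPE_STARTS = (0.5, 2.0, 8.0)
_BOUNDS_LO = (-1.0, -5.0, 1e-3, None)  # upper, lower, slope, midpoint
_BOUNDS_HI = (3.0, 1.0, 50.0, None)


def fit_curve(points: pd.DataFrame, flat_tol: float = 1e-9) -> DoseResponseCurve:
    """Least-squares 4PL fit of relative growth vs log10 dose.

    Multi-start over slope in {0.5, 2, 8} × midpoint at the x quartiles plus a
    data-driven default start; the best converged fit by SSE wins, ties going
    to the shallowest slope.  A constant response returns a flat sentinel with
    ``upper == lower``.
    """
    x = points["log10_dose"].to_numpy(float)
    g = points["g"].to_numpy(float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >=4 distinct doses")
    if np.ptp(x) < 2.0 - 1e-9:
        raise ValueError("doses must span >=2 log10 units")
    if np.ptp(g) < flat_tol:
        level = float(g.mean())
        return DoseResponseCurve(level, level, float("nan"), float("nan"), 0.0, is_flat=True)

    lo = (_BOUNDS_LO[0], _BOUNDS_LO[1], _BOUNDS_LO[2], x.min() - 3.0)
    hi = (_BOUNDS_HI[0], _BOUNDS_HI[1], _BOUNDS_HI[2], x.max() + 3.0)

    def resid(theta):
        return four_pl(x, *theta) - g

    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    starts = [(1.0, float(g.min()), s, m) for s in _SLOPE_STARTS for m in (q25, q50, q75)]
    starts.append((float(np.clip(g.max(), lo[0] + 1e-6, hi[0] - 1e-6)), float(np.clip(g.min(), lo[1] + 1e-6, hi[1] - 1e-6)), 2.0, float(q50)))

    best = None  # (sse, slope, theta)
    for theta0 in starts:
        theta0 = np.clip(theta0, np.array(lo) + 1e-9, np.array(hi) - 1e-9)
        try:
            res = least_squares(resid, theta0, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - scipy failures are rare
            continue
        if not res.success:
            continue
        sse = float(2 * res.cost)
        key = (sse, float(res.x[2]))
        if best is None or key < best[0]:
            best = (key, res.x)
    if best is None:
        raise FitError("4PL fit failed to converge from every start")
    upper, lower, slope, midpoint = (float(v) for v in best[1])
    if upper <= lower:
        level = float(g.mean())
        return DoseResponseCurve(level, level, float("nan"), float("nan"), float(np.std(g - level)), is_flat=True)
    residuals = four_pl(x, upper, lower, slope, midpoint) - g
    dof = max(len(g) - 4, 1)
    residual_sd = float(math.sqrt(float(residuals @ residuals) / dof))
    return DoseResponseCurve(upper, lower, slope, midpoint, residual_sd)


@dataclass
class SummaryStats:
    """The per-cell-line quintet T0, GI50, TGI, LC48, AUC0.

    Dose statistics are log10(µg/mL); thresholds not attained inside the tested
    range are clamped to the nearest range edge and flagged in ``censored``.
    ``ci`` maps statistic name to a percentile-bootstrap (2.5, 97.5) interval.
    """

    t0_h: float
    gi50: float
    tgi: float
    lc48: float
    auc0: float
    censored: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    n_boot_dropped: int = 0
    ci_warning: bool = False

    _STATS = ("t0_h", "gi50", "tgi", "lc48", "auc0")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._STATS}


def _threshold(curve: DoseResponseCurve, target: float, ladder: DoseLadder) -> tuple[float, bool]:
    """Solve g(x) = target; clamp to the tested range and flag censoring."""
    xstar = curve.solve(target)
    if math.isnan(xstar):  # flat curve: never crosses anything
        return ladder.log10_max, True
    if xstar > ladder.log10_max:
        return ladder.log10_max, True
    if xstar < ladder.log10_min:
        return ladder.log10_min, True
    return xstar, False


def _auc0(curve: DoseResponseCurve, ladder: DoseLadder, n_grid: int = 2001) -> float:
    """Trapezoid integral of max(100·g, 0) over the tested log10-dose range."""
    xs = np.linspace(ladder.log10_min, ladder.log10_max, n_grid)
    ys = np.maximum(100.0 * curve.predict(xs), 0.0)
    return float(np.trapezoid(ys, xs))


def summarize(curve: DoseResponseCurve, growth: GrowthParams, ladder: DoseLadder) -> SummaryStats:
    """Point estimates of T0, GI50, TGI, LC48 and AUC0 from a fitted curve.

    GI50 solves g = 0.5, TGI solves g = 0, LC48 solves g = -T0/dt (the dose at
    which the population halves over the exposure window); LC48 is unavailable
    when the control growth rate is non-positive.
    """
    cens: dict = {}
    gi50, cens["gi50"] = _threshold(curve, 0.5, ladder)
    tgi, cens["tgi"] = _threshold(curve, 0.0, ladder)
    if growth.defined:
        lc48, cens["lc48"] = _threshold(curve, -growth.doubling_time_h / growth.dt_h, ladder)
        t0 = growth.doubling_time_h
        cens["t0_h"] = False
    else:
        lc48, t0 = float("nan"), float("nan")
        cens["lc48"] = cens["t0_h"] = True
    auc0 = _auc0(curve, ladder)
    cens["auc0"] = False
    return SummaryStats(t0_h=t0, gi50=gi50, tgi=tgi, lc48=lc48, auc0=auc0, censored=cens)


def _resample_growth(growth: GrowthParams, rng: np.random.Generator) -> GrowthParams:
    """Parametric resample of the control log-absorbance means."""
    m0 = rng.normal(growth.log_a0_mean, growth.log_a0_sd / math.sqrt(growth.n0))
    m48 = rng.normal(growth.log_a48_mean, growth.log_a48_sd / math.sqrt(growth.n48))
    r0 = (m48 - m0) / growth.dt_h
    return replace(
        growth,
        rate_per_h=r0,
        doubling_time_h=math.log(2) / r0 if r0 > 0 else float("nan"),
        defined=r0 > 0,
    )


def bootstrap_cis(
    points: pd.DataFrame,
    curve: DoseResponseCurve,
    growth: GrowthParams,
    ladder: DoseLadder,
    B: int = 1000,
    seed: int | None = None,
) -> SummaryStats:
    """Parametric-bootstrap percentile CIs for all five summary statistics.

    Each replicate draws g* = ĝ(x) + N(0, residual_sd²) at the observed design
    points, refits the 4PL (warm-started at the base fit) and recomputes the
    statistics; T0 is resampled from the control log-absorbance summaries.
    Non-converged replicates are dropped and counted; more than 20% dropped
    sets ``ci_warning``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    base = summarize(curve, growth, ladder)
    x = points["log10_dose"].to_numpy(float)
    ghat = curve.predict(x)
    lo = (_BOUNDS_LO[0], _BOUNDS_LO[1], _BOUNDS_LO[2], x.min() - 3.0)
    hi = (_BOUNDS_HI[0], _BOUNDS_HI[1], _BOUNDS_HI[2], x.max() + 3.0)
    if curve.is_flat:
        theta_base = None
    else:
        theta_base = np.clip(
            [curve.upper, curve.lower, curve.slope, curve.midpoint],
            np.array(lo) + 1e-9,
            np.array(hi) - 1e-9,
        )
    draws: dict[str, list[float]] = {k: [] for k in SummaryStats._STATS}
    dropped = 0
    for _ in range(B):
        gstar = ghat + rng.normal(0.0, curve.residual_sd, size=len(x))
        gstar_growth = _resample_growth(growth, rng) if growth.defined else growth
        if curve.is_flat or np.ptp(gstar) < 1e-12:
            level = float(gstar.mean())
            cstar = DoseResponseCurve(level, level, float("nan"), float("nan"), 0.0, is_flat=True)
        else:
            def resid(theta, gstar=gstar):
                return four_pl(x, *theta) - gstar

            try:
                res = least_squares(resid, theta_base, bounds=(lo, hi), method="trf")
            except Exception:
                res = None
            if res is None or not res.success or res.x[0] <= res.x[1]:
                dropped += 1
                continue
            cstar = DoseResponseCurve(*(float(v) for v in res.x), residual_sd=curve.residual_sd)
        sstar = summarize(cstar, gstar_growth, ladder)
        for k in SummaryStats._STATS:
            draws[k].append(getattr(sstar, k))
    cis = {}
    for k, vals in draws.items():
        arr = np.asarray(vals, float)
        arr = arr[np.isfinite(arr)]
        if len(arr) == 0:
            cis[k] = (float("nan"), float("nan"))
        else:
            cis[k] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    base.ci = cis
    base.n_boot_dropped = dropped
    base.ci_warning = dropped > 0.2 * B
    if base.ci_warning:
        warnings.warn(f"{dropped}/{B} bootstrap replicates failed to converge", stacklevel=2)
    return base


class DoseResponseModel:
    """Dose-response model for one cell line × drug plate assay.

    Parameters
    ----------
    plate
        Well-level readings (two timepoints, geometric dose ladder, controls).
    ladder
        The dose ladder used on the plate; defaults to 16 two-fold dilutions
        from 500 µg/mL.
    background
        Optional blank absorbance subtracted from every reading before
        analysis (default 0: no blank subtraction).
    """

    def __init__(
        self,
        plate: PlateAssay,
        ladder: DoseLadder | None = None,
        background: float = 0.0,
    ):
        if background:
            plate = PlateAssay(plate.data.assign(absorbance=plate.data["absorbance"] - background))
        self.plate = plate
        self.ladder = ladder if ladder is not None else DoseLadder()
        self.background = background

    @classmethod
    def from_csv(cls, path, ladder: DoseLadder | None = None) -> "DoseResponseModel":
        return cls(PlateAssay.from_csv(path), ladder=ladder)

    def fit(self, bootstrap: int = 1000, seed: int | None = None) -> "DoseResponseResults":
        """Estimate growth, fit the 4PL and summarise; bootstrap=0 skips CIs."""
        growth = estimate_growth(self.plate)
        if not growth.defined:
            raise ValueError(
                f"{self.plate.cell_line}: controls did not grow; relative growth undefined"
            )
        points = relative_growth(self.plate, growth)
        curve = fit_curve(points)
        if bootstrap:
            stats = bootstrap_cis(points, curve, growth, self.ladder, B=bootstrap, seed=seed)
        else:
            stats = summarize(curve, growth, self.ladder)
        return DoseResponseResults(self, growth, points, curve, stats)


class DoseResponseResults:
    """Fitted dose-response curve and its summary statistics."""

    def __init__(self, model, growth, points, curve, stats):
        self.model = model
        self.growth = growth
        self.points = points
        self.curve = curve
        self.stats = stats

    @property
    def cell_line(self) -> str:
        return self.model.plate.cell_line

    def summary(self) -> pd.DataFrame:
        """One-row table mirroring the published screen summaries."""
        s = self.stats
        row = {"cell_line": self.cell_line, "drug": self.model.plate.drug}
        for k in SummaryStats._STATS:
            name = "t0" if k == "t0_h" else k
            row[name] = getattr(s, k)
            lo, hi = s.ci.get(k, (float("nan"), float("nan")))
            row[f"{name}_lo"], row[f"{name}_hi"] = lo, hi
        row["censored_flags"] = ";".join(k for k, v in s.censored.items() if v)
        return pd.DataFrame([row])

    def plot(self, ax=None):
        """Relative-growth points and the fitted curve on a log10-dose axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.points["log10_dose"], self.points["g"], s=12, alpha=0.7)
        xs = np.linspace(self.model.ladder.log10_min, self.model.ladder.log10_max, 200)
        ax.plot(xs, self.curve.predict(xs), color="C1")
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.set_xlabel("log10 dose (µg/mL)")
        ax.set_ylabel("relative growth g")
        ax.set_title(self.cell_line)
        return ax


def screen_to_table(
    plates: list[PlateAssay],
    B: int = 1000,
    seed: int | None = None,
    ladder: DoseLadder | None = None,
) -> pd.DataFrame:
    """Run the full chain for every plate; one summary row per cell line.

    Failures are reported per cell line in an ``error`` column rather than
    aborting the screen.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(plates)) if plates else []
    for plate, child in zip(plates, child_seeds):
        try:
            res = DoseResponseModel(plate, ladder=ladder).fit(
                bootstrap=B, seed=int(child.generate_state(1)[0] % (2**31))
            )
            row = res.summary().iloc[0].to_dict()
            row["error"] = ""
        except Exception as exc:
            row = {"cell_line": plate.cell_line, "drug": plate.drug, "error": str(exc)}
        rows.append(row)
    cols = ["cell_line", "drug"]
    if rows:
        for r in rows:
            for c in r:
                if c not in cols:
                    cols.append(c)
    return pd.DataFrame(rows, columns=cols if rows else None)
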