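"""Resistance gene signature: tertile labels, penalized training, prediction.

Cell lines are split, separately per disease, into AUC0 tertiles (sensitive /
intermediate / resistant).  The outer tertiles become a binary outcome
(resistant = 1) for an elastic-net penalized logistic regression on the
standardized expression matrix.  The penalty pair — mixing value a in
{0.1, ..., 1.0} and a 100-point log-spaced lambda path from the all-zero
lambda downward — is tuned by leave-one-out cross-validation with
misclassification at a 0.5 cutoff as the loss; ties prefer the sparser model
(largest lambda, then largest mixing value).  The genes with nonzero
coefficients in the final refit form the signature, and the fitted logistic
model assigns a resistance probability to any expression sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._enet import lambda_max, lambda_path, logistic_enet_path, standardize

__all__ = [
    "ResistanceLabel",
    "assign_tertiles",
    "tertile_sizes",
    "SignatureModel",
    "SignatureResults",
    "CvResult",
    "loocv_misclassification",
]

DEFAULT_ALPHAS = tuple(round(0.1 * k, 1) for k in range(1, 11))


@dataclass(frozen=True)
class ResistanceLabel:
    cell_line: str
    disease: str
    tertile: str  # {"sensitive", "intermediate", "resistant"}


def tertile_sizes(n: int) -> tuple[int, int, int]:
    """(sensitive, intermediate, resistant) sizes: floor(n/3) in the middle,
    remainder split across the outer groups with the extra one going low."""
    if n < 3:
        raise ValueError("need >=3 items for tertiles")
    mid = n // 3
    outer = n - mid
    low = (outer + 1) // 2
    return low, mid, outer - low


def assign_tertiles(summary: pd.DataFrame) -> list[ResistanceLabel]:
    """Per-disease AUC0 tertiles: lowest third sensitive, top third resistant.

    ``summary`` needs columns ``cell_line, disease, auc0``.  Within a disease,
    lines are sorted ascending by AUC0 with ties broken by a stable sort on
    cell-line name; sizes follow :func:`tertile_sizes` (14 -> 5/4/5,
    11 -> 4/3/4).
    """
    for col in ("cell_line", "disease", "auc0"):
        if col not in summary.columns:
            raise ValueError(f"summary table missing column {col!r}")
    if summary["auc0"].isna().any() or not np.isfinite(summary["auc0"]).all():
        raise ValueError("AUC0 must be finite for every cell line")
    labels: list[ResistanceLabel] = []
    for disease, sub in summary.groupby("disease", sort=True):
        n = len(sub)
        if n < 3:
            raise ValueError(f"disease {disease!r} has fewer than 3 cell lines")
        sub = sub.sort_values("cell_line", kind="stable").sort_values("auc0", kind="stable")
        n_sens, n_mid, _ = tertile_sizes(n)
        tert = ["sensitive"] * n_sens + ["intermediate"] * n_mid
        tert += ["resistant"] * (n - len(tert))
        labels.extend(
            ResistanceLabel(str(cl), str(disease), t)
            for cl, t in zip(sub["cell_line"], tert)
        )
    return labels


def loocv_misclassification(X: np.ndarray, y: np.ndarray, alpha: float, lams: np.ndarray) -> np.ndarray:
    """Per-fold LOOCV misclassification indicators, shape (n, len(lams)).

    Each fold re-standardizes its own n-1 training samples (the left-out
    sample never influences the fold's centering, scaling or fit) and scores
    the left-out sample at a 0.5 probability cutoff.  ``X`` is samples ×
    features on the raw scale.
    """
    n = len(y)
    miscls = np.zeros((n, len(lams)))
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, c_i, s_i = standardize(X[keep])
        b0s, coefs = logistic_enet_path(Xtr, y[keep], alpha, lams)
        zi = (X[i] - c_i) / s_i
        eta = b0s + coefs @ zi
        pred = (1.0 / (1.0 + np.exp(-eta)) > 0.5).astype(float)
        miscls[i] = pred != y[i]
    return miscls


@dataclass
class CvResult:
    """Leave-one-out misclassification over the (mixing, lambda) grid."""

    grid: pd.DataFrame  # columns: alpha, lambda, error
    alpha: float
    lam: float
    error: float
    tie_trace: list
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        errs = self.grid["error"].to_numpy()
        assert float(errs.min()) == self.error


class SignatureModel:
    """Elastic-net logistic resistance-signature model.

    Parameters
    ----------
    expr
        Log-scale expression, features × samples, unique feature ids as index.
    labels
        Tertile labels (:class:`ResistanceLabel` or a data frame with columns
        ``cell_line, disease, tertile``).  Intermediate lines are excluded
        from training; ``resistant`` is coded 1.
    diseases
        Optional subset of diseases to train on (default: pooled over all).
    """

    def __init__(self, expr: pd.DataFrame, labels, diseases=None):
        if isinstance(labels, pd.DataFrame):
            labels = [
                ResistanceLabel(str(r.cell_line), str(r.disease), str(r.tertile))
                for r in labels.itertuples()
            ]
        if diseases is not None:
            labels = [l for l in labels if l.disease in set(diseases)]
        included = [l for l in labels if l.tertile in ("sensitive", "resistant")]
        missing = [l.cell_line for l in included if l.cell_line not in expr.columns]
        if missing:
            raise ValueError(f"expression matrix lacks samples: {missing}")
        if len(included) < 4:
            raise ValueError("need >=4 sensitive/resistant cell lines to train")
        y = np.array([1.0 if l.tertile == "resistant" else 0.0 for l in included])
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.expr = expr
        self.labels = included
        self.sample_names = [l.cell_line for l in included]
        self.y = y
        self.X_raw = expr[self.sample_names].to_numpy(float).T  # samples × features
        self.feature_ids = list(expr.index)

    def fit(
        self,
        alphas=DEFAULT_ALPHAS,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
    ) -> "SignatureResults":
        """Tune (mixing, lambda) by LOOCV misclassification, then refit on all lines.

        The lambda sequence for each mixing value is computed on the full
        training data and shared across folds; each fold re-standardizes its
        own training samples so the left-out line never leaks into the fit.
        """
        X, y = self.X_raw, self.y
        n = len(y)
        Xs_full, center, scale = standardize(X)

        grid_rows = []
        paths = {}
        for alpha in alphas:
            lams = lambda_path(lambda_max(Xs_full, y, alpha), n_lambda, lambda_min_ratio)
            paths[alpha] = lams
            err = loocv_misclassification(X, y, alpha, lams).mean(axis=0)
            for l_idx, (lam, e) in enumerate(zip(lams, err)):
                grid_rows.append(
                    {
                        "alpha": float(alpha),
                        "lambda": float(lam),
                        "l_index": l_idx,
                        "error": float(e),
                    }
                )
        grid = pd.DataFrame(grid_rows)

        best = grid["error"].min()
        ties = grid[grid["error"] == best]
        # tie-break toward the more penalized model: largest lambda, then
        # largest mixing value
        chosen = ties.sort_values(
            ["lambda", "alpha"], ascending=[False, False], kind="stable"
        ).iloc[0]
        cv = CvResult(
            grid=grid,
            alpha=float(chosen["alpha"]),
            lam=float(chosen["lambda"]),
            error=float(best),
            tie_trace=ties[["alpha", "lambda"]].to_records(index=False).tolist(),
        )

        lams = paths[cv.alpha]
        l_idx = int(np.argmin(np.abs(lams - cv.lam)))
        b0s, coefs = logistic_enet_path(Xs_full, y, cv.alpha, lams[: l_idx + 1])
        return SignatureResults(
            model=self,
            feature_ids=self.feature_ids,
            center=center,
            scale=scale,
            intercept=float(b0s[-1]),
            coefficients=coefs[-1].copy(),
            mixing_a=cv.alpha,
            penalty_lambda=float(lams[l_idx]),
            cv_error=cv.error,
            cv_result=cv,
        )


class SignatureResults:
    """A fitted resistance signature.

    Coefficients are on the standardized-expression scale; prediction applies
    the stored training center/scale before the logistic link.  The signature
    is the set of features with nonzero coefficients.
    """

    def __init__(
        self,
        feature_ids,
        center,
        scale,
        intercept,
        coefficients,
        mixing_a,
        penalty_lambda,
        cv_error,
        model=None,
        cv_result=None,
    ):
        self.model = model
        self.feature_ids = list(feature_ids)
        self.center = np.asarray(center, float)
        self.scale = np.asarray(scale, float)
        self.intercept = float(intercept)
        self.coefficients = np.asarray(coefficients, float)
        self.mixing_a = float(mixing_a)
        self.penalty_lambda = float(penalty_lambda)
        self.cv_error = float(cv_error)
        self.cv_result = cv_result

    @property
    def signature(self) -> list[str]:
        return [f for f, c in zip(self.feature_ids, self.coefficients) if c != 0.0]

    def predict(self, expr: pd.DataFrame, impute_missing: bool = False) -> pd.DataFrame:
        """Resistance probability per sample of a features × samples matrix.

        All signature features must be present unless ``impute_missing`` is
        set, in which case absent features are imputed at their training mean
        (contributing zero to the score).
        """
        nz = self.coefficients != 0.0
        needed = [f for f, keep in zip(self.feature_ids, nz) if keep]
        missing = [f for f in needed if f not in expr.index]
        if missing and not impute_missing:
            raise ValueError(f"expression matrix lacks signature features: {missing[:5]}...")
        n_samples = expr.shape[1]
        z = np.zeros((len(self.feature_ids), n_samples))
        for k, (fid, keep) in enumerate(zip(self.feature_ids, nz)):
            if not keep:
                continue
            if fid in expr.index:
                vals = expr.loc[fid].to_numpy(float)
                z[k] = (vals - self.center[k]) / self.scale[k]
        eta = np.clip(self.intercept + self.coefficients @ z, -500, 500)
        prob = 1.0 / (1.0 + np.exp(-eta))
        out = pd.DataFrame({"sample_id": list(expr.columns), "resistance_prob": prob})
        return out

    def summary(self) -> pd.DataFrame:
        """Signature genes and their standardized-scale coefficients."""
        nz = self.coefficients != 0.0
        df = pd.DataFrame(
            {
                "feature_id": np.asarray(self.feature_ids, object)[nz],
                "coefficient": self.coefficients[nz],
            }
        ).sort_values("coefficient", key=np.abs, ascending=False, kind="stable")
        return df.reset_index(drop=True)

    def to_json(self, path=None) -> str | None:
        payload = {
            "feature_ids": self.feature_ids,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "mixing_a": self.mixing_a,
            "penalty_lambda": self.penalty_lambda,
            "cv_error": self.cv_error,
        }
        if self.cv_result is not None:
            payload["cv_grid"] = self.cv_result.grid.to_dict(orient="list")
            payload["cv_cutoff"] = self.cv_result.cutoff
        text = json.dumps(payload)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source) -> "SignatureResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cv = None
        if "cv_grid" in payload:
            grid = pd.DataFrame(payload["cv_grid"])
            best = grid["error"].min()
            ties = grid[grid["error"] == best]
            cv = CvResult(
                grid=grid,
                alpha=payload["mixing_a"],
                lam=payload["penalty_lambda"],
                error=float(best),
                tie_trace=ties[["alpha", "lambda"]].to_records(index=False).tolist(),
                cutoff=payload.get("cv_cutoff", 0.5),
            )
        return cls(
            feature_ids=payload["feature_ids"],
            center=payload["center"],
            scale=payload["scale"],
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            mixing_a=payload["mixing_a"],
            penalty_lambda=payload["penalty_lambda"],
            cv_error=payload["cv_error"],
            cv_result=cv,
        )
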