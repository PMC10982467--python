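"""Head-to-head evaluation of hybrid vs population-PK clearance predictions.

For each evaluation patient, both predictors are scored against the realized
individual clearance: the PPK population prediction (model at η = 0) and the
hybrid prediction (trained tree ensemble on the covariates). Per-patient
absolute errors |CL_pred − CL_true| (L/h) and relative errors
|CL_pred − CL_true| / CL_true are tabulated, a patient counts as *improved*
when the hybrid absolute error is strictly smaller than the PPK one, and the
summary reports the mean and (Q1, Q3) quartile interval of each error kind
per model (linear-interpolation quartiles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DomainError, StateError
from .ml import FittedModel
from .ppk import PPKParams, population_prediction

COMPARISON_COLUMNS = [
    "id",
    "cl_true_L_h",
    "cl_ppk_L_h",
    "cl_hybrid_L_h",
    "abs_err_ppk",
    "abs_err_hybrid",
    "rel_err_ppk",
    "rel_err_hybrid",
    "improved",
]


@dataclass(frozen=True)
class ModelErrorSummary:
    mean_abs_err: float
    abs_err_q1: float
    abs_err_q3: float
    mean_rel_err: float
    rel_err_q1: float
    rel_err_q3: float


@dataclass(frozen=True)
class ErrorSummary:
    """Mean and quartile-interval error summary per model."""

    ppk: ModelErrorSummary
    hybrid: ModelErrorSummary
    n: int

    def to_dict(self) -> dict:
        return {"ppk": asdict(self.ppk), "hybrid": asdict(self.hybrid), "n": self.n}


def absolute_error(cl_pred, cl_true):
    """|CL_pred − CL_true| in L/h; vectorized."""
    pred = np.asarray(cl_pred, dtype=float)
    true = np.asarray(cl_true, dtype=float)
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(true))):
        raise DomainError("clearances must be finite")
    out = np.abs(pred - true)
    return float(out) if out.ndim == 0 else out


def relative_error(cl_pred, cl_true):
    """|CL_pred − CL_true| / CL_true (dimensionless); requires CL_true > 0."""
    true = np.asarray(cl_true, dtype=float)
    if np.any(true <= 0):
        raise DomainError("true clearance must be > 0 for relative error")
    out = absolute_error(cl_pred, cl_true) / true
    return float(out) if np.ndim(out) == 0 else out


def compare(
    eval_cohort: pd.DataFrame,
    hybrid: FittedModel,
    params: PPKParams | None = None,
) -> pd.DataFrame:
    """Score both predictors per patient against realized clearance.

    Returns a :data:`COMPARISON_COLUMNS` frame; ``improved`` is True where
    the hybrid absolute error is strictly below the PPK absolute error.
    """
    params = params or PPKParams()
    cl_true = eval_cohort["cl_true_L_h"].to_numpy(dtype=float)
    if np.isnan(cl_true).any():
        raise StateError("evaluation cohort is missing realized clearances")
    cl_ppk = population_prediction(eval_cohort, params)
    cl_hybrid = hybrid.predict(eval_cohort)
    abs_ppk = absolute_error(cl_ppk, cl_true)
    abs_hyb = absolute_error(cl_hybrid, cl_true)
    return pd.DataFrame(
        {
            "id": eval_cohort["id"].to_numpy(),
            "cl_true_L_h": cl_true,
            "cl_ppk_L_h": cl_ppk,
            "cl_hybrid_L_h": cl_hybrid,
            "abs_err_ppk": abs_ppk,
            "abs_err_hybrid": abs_hyb,
            "rel_err_ppk": relative_error(cl_ppk, cl_true),
            "rel_err_hybrid": relative_error(cl_hybrid, cl_true),
            "improved": abs_hyb < abs_ppk,
        }
    )


def improvement_fraction(comparison: pd.DataFrame) -> float:
    """Share of patients whose hybrid prediction beats the PPK prediction."""
    if len(comparison) == 0:
        raise StateError("comparison table is empty")
    return float(comparison["improved"].mean())


def _summarize(abs_err: np.ndarray, rel_err: np.ndarray) -> ModelErrorSummary:
    a_q1, a_q3 = np.percentile(abs_err, [25, 75])  # linear interpolation
    r_q1, r_q3 = np.percentile(rel_err, [25, 75])
    return ModelErrorSummary(
        mean_abs_err=float(abs_err.mean()),
        abs_err_q1=float(a_q1),
        abs_err_q3=float(a_q3),
        mean_rel_err=float(rel_err.mean()),
        rel_err_q1=float(r_q1),
        rel_err_q3=float(r_q3),
    )


def summarize_errors(comparison: pd.DataFrame) -> ErrorSummary:
    """Mean and (Q1, Q3) of absolute and relative errors, per model."""
    if len(comparison) == 0:
        raise StateError("comparison table is empty")
    return ErrorSummary(
        ppk=_summarize(
            comparison["abs_err_ppk"].to_numpy(), comparison["rel_err_ppk"].to_numpy()
        ),
        hybrid=_summarize(
            comparison["abs_err_hybrid"].to_numpy(), comparison["rel_err_hybrid"].to_numpy()
        ),
        n=len(comparison),
    )


def summary_to_json(summary: ErrorSummary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_diagnostics(comparison: pd.DataFrame, out_dir) -> dict[str, str]:
    """Write the three diagnostic figures plus companion data CSVs.

    * ``residuals`` — per-patient residuals (predicted − true) for both models
    * ``prediction_scatter`` — hybrid vs PPK predictions with the y = x line
    * ``actual_vs_predicted`` — true vs predicted clearance per model, y = x line

    Each figure ``<name>.png`` is accompanied by ``<name>.csv`` holding
    exactly the plotted values. Returns name → figure path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if len(comparison) == 0:
        raise StateError("comparison table is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    ids = comparison["id"].to_numpy()
    true = comparison["cl_true_L_h"].to_numpy()
    ppk = comparison["cl_ppk_L_h"].to_numpy()
    hyb = comparison["cl_hybrid_L_h"].to_numpy()

    # residuals per patient
    res = pd.DataFrame(
        {"id": ids, "resid_ppk": ppk - true, "resid_hybrid": hyb - true}
    )
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(res["id"], res["resid_ppk"], s=12, alpha=0.7, label="PPK")
    ax.scatter(res["id"], res["resid_hybrid"], s=12, alpha=0.7, label="hybrid")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("patient id")
    ax.set_ylabel("residual (L/h)")
    ax.legend()
    fig.savefig(out / "residuals.png", dpi=120)
    plt.close(fig)
    res.to_csv(out / "residuals.csv", index=False, float_format="%.17g")
    paths["residuals"] = str(out / "residuals.png")

    # hybrid vs ppk predictions
    sc = pd.DataFrame({"id": ids, "cl_ppk_L_h": ppk, "cl_hybrid_L_h": hyb})
    lim = (0.0, max(ppk.max(), hyb.max()) * 1.05)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(ppk, hyb, s=12, alpha=0.7)
    ax.plot(lim, lim, color="red", lw=1.0)
    ax.set_xlabel("PPK prediction (L/h)")
    ax.set_ylabel("hybrid prediction (L/h)")
    fig.savefig(out / "prediction_scatter.png", dpi=120)
    plt.close(fig)
    sc.to_csv(out / "prediction_scatter.csv", index=False, float_format="%.17g")
    paths["prediction_scatter"] = str(out / "prediction_scatter.png")

    # actual vs predicted, per model
    ap = pd.DataFrame(
        {"id": ids, "cl_true_L_h": true, "cl_ppk_L_h": ppk, "cl_hybrid_L_h": hyb}
    )
    lim = (0.0, max(true.max(), ppk.max(), hyb.max()) * 1.05)
    fig, axes = plt.subplots(1, 2, figsize=(10, 5), sharex=True, sharey=True)
    for ax, pred, label in ((axes[0], ppk, "PPK"), (axes[1], hyb, "hybrid")):
        ax.scatter(pred, true, s=12, alpha=0.7)
        ax.plot(lim, lim, color="red", lw=1.0)
        ax.set_xlabel(f"{label} prediction (L/h)")
    axes[0].set_ylabel("realized CL (L/h)")
    fig.savefig(out / "actual_vs_predicted.png", dpi=120)
    plt.close(fig)
    ap.to_csv(out / "actual_vs_predicted.csv", index=False, float_format="%.17g")
    paths["actual_vs_predicted"] = str(out / "actual_vs_predicted.png")
    return paths
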