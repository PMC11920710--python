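"""Error metrics for per-point TAWSS prediction: MRE and NAME.

MRE (mean relative error) averages the per-point relative deviation
|y_i - yhat_i| / |y_i| over one model, in percent.  NAME (normalized
absolute mean error) averages |y_i - yhat_i| normalized by the
dataset-global TAWSS range max{y} - min{y}, where the extremes are taken
over every model in the generated dataset, in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MetricReport", "mre", "name_metric", "evaluate_split"]

_EPS = 1e-12


class MetricDomainError(ValueError):
    pass


def mre(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean relative error in percent: mean_i |y_i - yhat_i| / |y_i| * 100.

    (The square root of the squared ratio in the textbook formulation is
    algebraically the absolute value.)
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise MetricDomainError(f"shape mismatch {y.shape} vs {yhat.shape}")
    small = np.abs(y) <= _EPS
    if small.any():
        raise MetricDomainError(
            f"reference values ~0 at indices {np.flatnonzero(small)[:10].tolist()}"
        )
    return float(np.mean(np.abs(y - yhat) / np.abs(y)) * 100.0)


def name_metric(y: np.ndarray, yhat: np.ndarray, global_max: float, global_min: float) -> float:
    """Normalized absolute mean error in percent against the global range."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise MetricDomainError(f"shape mismatch {y.shape} vs {yhat.shape}")
    if not global_max > global_min:
        raise MetricDomainError(f"global_max {global_max} <= global_min {global_min}")
    return float(np.mean(np.abs(y - yhat)) / (global_max - global_min) * 100.0)


@dataclass
class MetricReport:
    """Per-model MRE/NAME plus their mean and std across models."""

    model_ids: list[str]
    mre_per_model: list[float]
    name_per_model: list[float]
    global_max: float
    global_min: float
    n_points: int = 0

    @property
    def mre_mean(self) -> float:
        return float(np.mean(self.mre_per_model))

    @property
    def mre_std(self) -> float:
        return float(np.std(self.mre_per_model))

    @property
    def name_mean(self) -> float:
        return float(np.mean(self.name_per_model))

    @property
    def name_std(self) -> float:
        return float(np.std(self.name_per_model))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model_id": self.model_ids, "mre": self.mre_per_model, "name": self.name_per_model}
        )

    def summary(self) -> dict:
        return {
            "n_models": len(self.model_ids),
            "n_points": self.n_points,
            "mre_mean": self.mre_mean,
            "mre_std": self.mre_std,
            "name_mean": self.name_mean,
            "name_std": self.name_std,
            "global_max": self.global_max,
            "global_min": self.global_min,
        }

    def save(self, json_path: str | Path, csv_path: str | Path | None = None) -> None:
        payload = self.summary()
        payload["per_model"] = {
            m: {"mre": r, "name": n}
            for m, r, n in zip(self.model_ids, self.mre_per_model, self.name_per_model)
        }
        Path(json_path).write_text(json.dumps(payload, indent=1))
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)


def evaluate_split(
    truths: dict[str, np.ndarray],
    predictions: dict[str, np.ndarray],
    global_max: float,
    global_min: float,
) -> MetricReport:
    """Per-model metrics for matching truth/prediction dictionaries."""
    ids = sorted(truths)
    if sorted(predictions) != ids:
        raise MetricDomainError("truth and prediction model ids differ")
    mres = [mre(truths[m], predictions[m]) for m in ids]
    names = [name_metric(truths[m], predictions[m], global_max, global_min) for m in ids]
    n_points = sum(len(truths[m]) for m in ids)
    return MetricReport(
        model_ids=ids,
        mre_per_model=mres,
        name_per_model=names,
        global_max=global_max,
        global_min=global_min,
        n_points=n_points,
    )
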