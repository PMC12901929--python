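"""Cohort-level modelling interface.

`BinauralSRTModel` wraps a listener cohort plus the prediction engine the way
a statistical model wraps data: construct it from listeners (or from the
audiogram/measured-SRT files), call :meth:`fit` with an individualization
method, and receive a :class:`CohortResults` carrying the per-listener
predictions, the derived benefits, accuracy metrics, outlier screen and
pattern-projection analysis, plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Listener, listeners_from_files, simulate_measured_srts
from .srt import CONDITIONS, SolverConfig, SRTEngine
from . import stats as bstats


class BinauralSRTModel:
    """Predict speech recognition thresholds for a cohort of listeners.

    Parameters
    ----------
    listeners : list of Listener
        Cohort with audiograms; measured SRTs are required on each listener
        for the ISC methods and for accuracy metrics.
    engine : SRTEngine, optional
        Preconfigured engine (shared caches); built from ``solver`` otherwise.
    seed : int
        Master seed for scene synthesis and Monte-Carlo jitter.
    """

    def __init__(
        self,
        listeners: list[Listener],
        engine: SRTEngine | None = None,
        solver: SolverConfig | None = None,
        seed: int = 0,
    ) -> None:
        if not listeners:
            raise ValueError("cohort must contain at least one listener")
        self.listeners = listeners
        self.engine = engine or SRTEngine(solver=solver)
        self.seed = int(seed)

    @classmethod
    def from_files(
        cls,
        audiogram_csv,
        measured_tsv=None,
        solver: SolverConfig | None = None,
        seed: int = 0,
    ) -> "BinauralSRTModel":
        return cls(listeners_from_files(audiogram_csv, measured_tsv), solver=solver, seed=seed)

    def simulate_measurements(self, measurement_noise_sd_db: float = 1.0) -> None:
        """Attach synthetic "measured" SRTs (model + ISC ground truth + noise)."""
        for i, listener in enumerate(self.listeners):
            simulate_measured_srts(
                listener,
                self.engine,
                measurement_noise_sd_db=measurement_noise_sd_db,
                seed=self.seed,
            )

    def fit(self, method: str = "none", conditions: tuple = CONDITIONS) -> "CohortResults":
        """Run the predictor for every listener; returns the results object.

        For ISC methods the common-reference (method ``none``) predictions
        are computed alongside: the masking-release benefits reported by the
        results object are taken from those, because a condition-independent
        individual component cancels in SRT differences (the ISC only
        recalibrates absolute SRTs).
        """
        table, errors = self._predict_table(method, conditions)
        baseline = table
        if method != "none":
            baseline, _ = self._predict_table("none", conditions)
        return CohortResults(model=self, method=method, table=table,
                             baseline_table=baseline, errors=errors)

    def _predict_table(self, method: str, conditions: tuple) -> tuple[pd.DataFrame, list]:
        rows = []
        errors = []
        for listener in self.listeners:
            try:
                results = self.engine.predict_all(listener, method, self.seed, conditions=conditions)
            except ValueError as exc:
                errors.append((listener.id, str(exc)))
                continue
            for res in results:
                rows.append(
                    (
                        listener.id,
                        listener.group,
                        res.condition,
                        listener.measured_srts.get(res.condition, np.nan),
                        res.srt_db,
                        res.method,
                        res.reference_sii_used,
                        res.noise_increment_db,
                        ";".join(res.flags),
                    )
                )
        table = pd.DataFrame(
            rows,
            columns=[
                "id", "group", "condition", "measured_srt_db", "predicted_srt_db",
                "method", "reference_sii", "noise_increment_db", "flags",
            ],
        )
        return table, errors


@dataclass
class CohortResults:
    """Predictions and evaluation statistics for one fitted method."""

    model: BinauralSRTModel
    method: str
    table: pd.DataFrame
    baseline_table: pd.DataFrame | None = None
    errors: list = field(default_factory=list)

    # -- derived frames ----------------------------------------------------

    def _long(self, col: str, table: pd.DataFrame | None = None) -> pd.DataFrame:
        table = self.table if table is None else table
        out = table[["id", "group", "condition", col]].rename(columns={col: "srt_db"})
        return out.dropna(subset=["srt_db"])

    def benefits(self, which: str = "predicted") -> pd.DataFrame:
        """SRM/BRM/BEL per listener from predicted or measured SRTs.

        Predicted benefits are always derived from the common-reference
        predictions: a condition-independent suprathreshold component shifts
        every condition's SRT equally, so it is compensated in the
        differences and the ISC calibration does not enter them.
        """
        if which == "predicted":
            table = self.baseline_table if self.baseline_table is not None else self.table
            return bstats.compute_benefits(self._long("predicted_srt_db", table))
        return bstats.compute_benefits(self._long("measured_srt_db"))

    def metrics(self) -> pd.DataFrame:
        """R^2 / bias / RMSE per condition and benefit (predictive rows only).

        For ISC methods the S0N0 column is a fit, not a prediction; it is
        retained but flagged in the summary.
        """
        baseline = None
        if self.baseline_table is not None:
            baseline = self._long("predicted_srt_db", self.baseline_table)
        return bstats.metrics_table(
            self._long("measured_srt_db"), self._long("predicted_srt_db"), baseline
        )

    def prediction_errors(self, condition: str) -> pd.Series:
        sub = self.table[self.table["condition"] == condition].dropna(subset=["measured_srt_db"])
        return (sub["measured_srt_db"] - sub["predicted_srt_db"]).rename("error_db")

    def outliers(self, condition: str = "S0N90") -> pd.DataFrame:
        err = self.prediction_errors(condition)
        idx = bstats.detect_outliers(err.to_numpy())
        sub = self.table[self.table["condition"] == condition].dropna(subset=["measured_srt_db"])
        return sub.iloc[idx][["id", "group", "measured_srt_db", "predicted_srt_db"]]

    def ks_normality(self, condition: str = "S0N90") -> float:
        return bstats.ks_normality(self.prediction_errors(condition).to_numpy())

    def pattern_projection(self, alpha: float = 0.05, min_group_n: int = 3) -> pd.DataFrame:
        return bstats.pattern_projection(
            self.benefits("measured"), self.benefits("predicted"), alpha, min_group_n
        )

    # -- presentation ------------------------------------------------------

    def plot_predictions(self, condition: str = "S0N90", ax=None):
        """Scatter of measured vs predicted SRTs with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        sub = self.table[self.table["condition"] == condition].dropna(subset=["measured_srt_db"])
        ax.scatter(sub["predicted_srt_db"], sub["measured_srt_db"], s=18, alpha=0.7)
        lo = min(sub["predicted_srt_db"].min(), sub["measured_srt_db"].min()) - 1
        hi = max(sub["predicted_srt_db"].max(), sub["measured_srt_db"].max()) + 1
        ax.plot([lo, hi], [lo, hi], "k-", lw=1)
        ax.set_xlabel("predicted SRT (dB SNR)")
        ax.set_ylabel("measured SRT (dB SNR)")
        ax.set_title(f"{condition} ({self.method})")
        return ax

    def plot_benefits(self, which: str = "predicted", ax=None):
        """Boxplots of SRM/BRM/BEL per hearing-loss group."""
        import matplotlib.pyplot as plt

        ben = self.benefits(which)
        groups = [g for g in ben["group"].dropna().unique()]
        fig = None
        if ax is None:
            fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
        else:
            axes = ax
        for a, measure in zip(axes, ("SRM", "BRM", "BEL")):
            data = [ben.loc[ben["group"] == g, measure] for g in groups]
            a.boxplot(data, tick_labels=groups)
            a.set_title(f"{which} {measure}")
            a.set_ylabel("dB")
        if fig is not None:
            fig.tight_layout()
        return axes

    def summary(self) -> str:
        lines = []
        n_listeners = self.table["id"].nunique()
        lines.append("Binaural SRT prediction results")
        lines.append("=" * 46)
        lines.append(f"method:            {self.method}")
        lines.append(f"listeners:         {n_listeners}")
        lines.append(f"conditions:        {', '.join(self.table['condition'].unique())}")
        if self.errors:
            lines.append(f"failed listeners:  {len(self.errors)}")
        has_measured = self.table["measured_srt_db"].notna().any()
        if has_measured:
            lines.append("")
            lines.append("accuracy (measured vs predicted)")
            lines.append("-" * 46)
            try:
                lines.append(self.metrics().round(3).to_string())
            except ValueError:
                lines.append("  (insufficient data)")
            if self.method != "none":
                lines.append("note: S0N0 is fitted (calibration), not predicted")
        lines.append("")
        lines.append("predicted SRT (dB SNR) by condition")
        lines.append("-" * 46)
        pivot = self.table.groupby("condition")["predicted_srt_db"].agg(
            mean="mean", sd="std", n="count"
        )
        lines.append(pivot.round(2).to_string())
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CohortResults method={self.method!r} n={self.table['id'].nunique()}>"
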