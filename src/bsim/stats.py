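"""Benefit decomposition and cohort accuracy statistics.

From the three spatial conditions the per-listener masking-release benefits
are derived as SRT differences:

    SRM = SRT(S0N0)   - SRT(S0N90)     spatial release from masking
    BRM = SRT(S0mN90m) - SRT(S0N90)    binaural release from masking
    BEL = SRT(S0N0)   - SRT(S0mN90m)   better-ear listening

so that SRM = BEL + BRM holds as an algebraic identity.  Prediction accuracy
is summarized by R^2 (squared Pearson correlation), bias (mean of measured
minus predicted) and RMSE; R^2 values are compared with Fisher's
Z-transformation on the correlations.  Outliers in the prediction errors are
flagged with Tukey's fences (1.5 x IQR) and normality is screened with a KS
test against a normal with sample mean/SD (parameters are estimated from the
data, so the p-values carry the usual Lilliefors-style caveat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

BENEFITS = ("SRM", "BRM", "BEL")
#: group ordering by severity: pairwise comparisons always put the
#: lower-loss group first
GROUP_ORDER = ("NH", "N1", "N2", "N3", "N4", "S1", "S2", "S3")


# ---------------------------------------------------------------------------
# benefits
# ---------------------------------------------------------------------------

def compute_benefits(srt_table: pd.DataFrame) -> pd.DataFrame:
    """Per-listener SRM/BRM/BEL from a long table of SRTs.

    ``srt_table`` needs columns ``id, condition, srt_db`` (plus optional
    ``group``).  Listeners missing any of the three conditions are dropped
    (with the reason recorded in the returned frame's ``attrs['dropped']``).
    """
    required = {"S0N0", "S0N90", "S0mN90m"}
    rows = []
    dropped = []
    for lid, sub in srt_table.groupby("id", sort=False):
        conds = dict(zip(sub["condition"], sub["srt_db"]))
        if not required.issubset(conds):
            dropped.append((lid, "missing condition(s): " + ",".join(sorted(required - set(conds)))))
            continue
        srm = conds["S0N0"] - conds["S0N90"]
        brm = conds["S0mN90m"] - conds["S0N90"]
        bel = conds["S0N0"] - conds["S0mN90m"]
        group = sub["group"].iloc[0] if "group" in sub else None
        rows.append((lid, group, srm, brm, bel))
    out = pd.DataFrame(rows, columns=["id", "group", "SRM", "BRM", "BEL"])
    out.attrs["dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------

@dataclass
class AccuracyMetrics:
    r2: float
    bias_db: float
    rmse_db: float
    n: int
    r2_defined: bool = True


def accuracy_metrics(measured, predicted) -> AccuracyMetrics:
    """R^2, bias and RMSE between measured and predicted values.

    bias = mean(measured - predicted); RMSE = sqrt(mean((measured -
    predicted)^2)), so rmse >= |bias| always.  Zero variance in either input
    leaves R^2 undefined (flagged, reported as nan).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.size != p.size or m.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    err = m - p
    bias = float(np.mean(err))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.std(m) == 0.0 or np.std(p) == 0.0:
        if np.allclose(m, p):
            return AccuracyMetrics(1.0, bias, rmse, m.size, r2_defined=False)
        return AccuracyMetrics(np.nan, bias, rmse, m.size, r2_defined=False)
    r = float(np.corrcoef(m, p)[0, 1])
    return AccuracyMetrics(r * r, bias, rmse, m.size)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p-value for the difference of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).  When comparing
    R^2 values, pass r = +sqrt(R^2) (positive sign convention).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * spstats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# outliers and normality
# ---------------------------------------------------------------------------

def tukey_fences(values, k: float = 1.5) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25.0, 75.0])  # linear-interpolation quartiles
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def detect_outliers(prediction_errors, k: float = 1.5) -> np.ndarray:
    """Indices falling outside Tukey's fences (Q1 - k*IQR, Q3 + k*IQR)."""
    v = np.asarray(prediction_errors, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile fences")
    lo, hi = tukey_fences(v, k)
    return np.where((v < lo) | (v > hi))[0]


def ks_normality(prediction_errors) -> float:
    """KS p-value against a normal with the sample's mean and SD."""
    v = np.asarray(prediction_errors, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 values for the KS screen")
    mu, sd = float(np.mean(v)), float(np.std(v, ddof=1))
    if sd == 0.0:
        return 0.0
    return float(spstats.kstest(v, "norm", args=(mu, sd)).pvalue)


# ---------------------------------------------------------------------------
# pattern projection
# ---------------------------------------------------------------------------

#: outcome codes: B=both, M=measured only (type II), P=predicted only (type I),
#: '.'=neither; +/- is the direction (first group's mean greater/smaller)
OUTCOME_CODES = {
    ("both", "greater"): "B+", ("both", "smaller"): "B-",
    ("measured_only", "greater"): "M+", ("measured_only", "smaller"): "M-",
    ("predicted_only", "greater"): "P+", ("predicted_only", "smaller"): "P-",
    ("none", None): ".",
}


def _one_sided_pair(a: np.ndarray, b: np.ndarray, alpha: float) -> str | None:
    """Direction in which group a (lower loss) differs from group b, if any.

    Two one-sided Welch t-tests; returns 'greater', 'smaller' or None.
    """
    greater = spstats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
    smaller = spstats.ttest_ind(a, b, equal_var=False, alternative="less").pvalue
    if greater < alpha:
        return "greater"
    if smaller < alpha:
        return "smaller"
    return None


def pattern_projection(
    benefits_measured: pd.DataFrame,
    benefits_predicted: pd.DataFrame,
    alpha: float = 0.05,
    min_group_n: int = 3,
) -> pd.DataFrame:
    """Group-pair significance pattern match between measured and predicted benefits.

    For every ordered group pair (lower-loss group first) and every measure,
    both one-sided Welch tests are run on the measured and on the predicted
    values and the cell is classified as ``both`` (same significant
    direction), ``measured_only`` (type II), ``predicted_only`` (type I),
    ``discordant`` (significant in opposite directions) or ``none``.  The
    result frame carries the match fraction in ``attrs['match_fraction']``
    and excluded groups in ``attrs['excluded_groups']``.
    """
    groups_m = {g: sub for g, sub in benefits_measured.groupby("group") if len(sub) >= min_group_n}
    groups_p = {g: sub for g, sub in benefits_predicted.groupby("group") if len(sub) >= min_group_n}
    usable = [g for g in GROUP_ORDER if g in groups_m and g in groups_p]
    excluded = [g for g in GROUP_ORDER if g in set(benefits_measured["group"]) and g not in usable]
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with sufficient n")

    rows = []
    matches = 0
    total = 0
    for ia, ga in enumerate(usable):
        for gb in usable[ia + 1 :]:
            for measure in BENEFITS:
                dm = _one_sided_pair(
                    groups_m[ga][measure].to_numpy(), groups_m[gb][measure].to_numpy(), alpha
                )
                dp = _one_sided_pair(
                    groups_p[ga][measure].to_numpy(), groups_p[gb][measure].to_numpy(), alpha
                )
                if dm is None and dp is None:
                    outcome, direction, code = "none", None, "."
                elif dm is not None and dp == dm:
                    outcome, direction = "both", dm
                    code = OUTCOME_CODES[(outcome, direction)]
                elif dm is not None and dp is None:
                    outcome, direction = "measured_only", dm
                    code = OUTCOME_CODES[(outcome, direction)]
                elif dm is None and dp is not None:
                    outcome, direction = "predicted_only", dp
                    code = OUTCOME_CODES[(outcome, direction)]
                else:  # both significant, opposite directions
                    outcome, direction, code = "discordant", dm, "X"
                total += 1
                if outcome in ("both", "none"):
                    matches += 1
                rows.append((ga, gb, measure, outcome, direction, code))

    out = pd.DataFrame(rows, columns=["group_a", "group_b", "measure", "outcome", "direction", "code"])
    out.attrs["match_fraction"] = matches / total if total else np.nan
    out.attrs["excluded_groups"] = excluded
    return out


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def metrics_table(
    measured: pd.DataFrame,
    predicted: pd.DataFrame,
    predicted_for_benefits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Accuracy metrics per condition and benefit (rows R^2/bias/RMSE).

    Inputs are long tables with columns ``id, condition, srt_db`` (measured)
    and the same for predicted; benefit columns are derived internally.
    ``predicted_for_benefits`` may supply a different prediction set for the
    benefit columns (e.g. common-reference predictions when the SRT columns
    come from an ISC calibration).
    """
    merged = measured.merge(predicted, on=["id", "condition"], suffixes=("_m", "_p"))
    cols = {}
    for cond in ("S0N0", "S0N90", "S0mN90m"):
        sub = merged[merged["condition"] == cond]
        if len(sub) >= 3:
            met = accuracy_metrics(sub["srt_db_m"], sub["srt_db_p"])
            cols[cond] = [met.r2, met.bias_db, met.rmse_db]
    bm = compute_benefits(measured)
    bp = compute_benefits(predicted_for_benefits if predicted_for_benefits is not None else predicted)
    joined = bm.merge(bp, on="id", suffixes=("_m", "_p"))
    for meas in BENEFITS:
        if len(joined) >= 3:
            met = accuracy_metrics(joined[f"{meas}_m"], joined[f"{meas}_p"])
            cols[meas] = [met.r2, met.bias_db, met.rmse_db]
    return pd.DataFrame(cols, index=["R2", "bias_db", "rmse_db"])


def write_pattern_tsv(pattern: pd.DataFrame, path) -> None:
    pattern.to_csv(path, sep="\t", index=False)
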