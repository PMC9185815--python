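"""CA19-9 coding and score fusion, specificity-targeted threshold calibration,
frozen external evaluation and score-covariate diagnostics.

CA19-9 is coded 1 for serum levels strictly above 37 U/mL and 0 otherwise —
including "not available", so a missing measurement can only lower, never
raise, a combined score.  The OR combination adds the code to the mean
cross-validated microbiome score (a positive on either axis lifts the
sample); the AND combination multiplies (both must fire).  Both operate on
ranks downstream, so the unbounded [0, 2] range of the OR score is harmless.

The decision threshold is calibrated on training-control scores to a target
specificity (default 90%, i.e. a 10% false-positive rate) and then carried
unchanged to external cohorts, where per-status-group flagging rates measure
sensitivity (PDAC groups) and cross-disease specificity (everything else).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import TrainedEnsemble, predict_ensemble

__all__ = [
    "encode_ca199",
    "combine_or",
    "combine_and",
    "ThresholdCalibration",
    "calibrate_threshold",
    "evaluate_external",
    "score_covariate_diagnostics",
]

CA199_THRESHOLD_UML = 37.0


def encode_ca199(levels, threshold: float = CA199_THRESHOLD_UML) -> pd.Series:
    """Binary-code serum CA19-9: 1 above ``threshold`` U/mL, 0 for negative or
    not available.  Exactly 37 U/mL is coded negative (strict inequality)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    lv = pd.Series(levels, dtype=float)
    if (lv.dropna() < 0).any():
        raise ValueError("negative CA19-9 level")
    return (lv > threshold).fillna(False).astype(int)


def _aligned(cv_scores: pd.Series, codes: pd.Series) -> tuple[pd.Series, pd.Series]:
    if set(cv_scores.index) != set(codes.index):
        raise ValueError("score and code sample sets differ")
    return cv_scores, codes.reindex(cv_scores.index)


def combine_or(cv_scores: pd.Series, codes: pd.Series) -> pd.Series:
    """OR combination: score + code (either signal suffices to rank high)."""
    s, c = _aligned(cv_scores, codes)
    return s + c


def combine_and(cv_scores: pd.Series, codes: pd.Series) -> pd.Series:
    """AND combination: score * code (both signals required)."""
    s, c = _aligned(cv_scores, codes)
    return s * c


@dataclass(frozen=True)
class ThresholdCalibration:
    threshold: float
    target_specificity: float
    achieved_fpr_train: float
    n_controls: int


def calibrate_threshold(
    control_scores, target_specificity: float = 0.90
) -> ThresholdCalibration:
    """Smallest score cut-off t with fraction(control scores > t) <= 1 - target.

    With n distinct control scores and target specificity 0.90, exactly
    floor(0.10 * n) controls end up flagged.  Flagging downstream uses the
    same strict ``> t`` comparison.
    """
    s = np.sort(np.asarray(control_scores, dtype=float))
    n = len(s)
    if n < 10:
        warnings.warn(f"only {n} controls; threshold granularity is coarse", stacklevel=2)
    if not 0 < target_specificity <= 1:
        raise ValueError("target_specificity must be in (0, 1]")
    # integer flag budget avoids float fuzz at exact boundaries like 1/10
    k_allowed = int(np.floor(n * (1.0 - target_specificity) + 1e-9))
    for t in s:
        count = int((s > t).sum())
        if count <= k_allowed:
            return ThresholdCalibration(float(t), target_specificity, count / n, n)
    raise AssertionError("unreachable: the maximum score always satisfies the target")


def evaluate_external(
    ensemble: TrainedEnsemble,
    calib: ThresholdCalibration,
    profile: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Score an external cohort with the frozen ensemble and count flags.

    Returns one row per (cohort, status group) plus a pooled ``NON_PDAC``
    row per cohort, with columns ``cohort, status, n, n_flagged, rate,
    model_variant``: the rate is a false-positive rate for non-PDAC groups
    and a recall for PDAC groups.
    """
    scores = predict_ensemble(ensemble, profile)
    meta = metadata.loc[scores.index]
    flagged = scores > calib.threshold
    rows = []
    groups = meta.groupby(["cohort", "group"], sort=True)
    for (cohort, status), idx in groups.groups.items():
        f = int(flagged.loc[idx].sum())
        rows.append({"cohort": cohort, "status": status, "n": len(idx),
                     "n_flagged": f, "rate": f / len(idx)})
    for cohort, sub in meta.groupby("cohort", sort=True):
        idx = sub.index[sub["group"] != "PDAC"]
        if len(idx):
            f = int(flagged.loc[idx].sum())
            rows.append({"cohort": cohort, "status": "NON_PDAC", "n": len(idx),
                         "n_flagged": f, "rate": f / len(idx)})
    out = pd.DataFrame(rows)
    out["model_variant"] = ensemble.variant
    return out


def score_covariate_diagnostics(scores: pd.Series, metadata: pd.DataFrame) -> pd.DataFrame:
    """Association checks of prediction scores with age, sex and sequencing depth.

    Spearman rank correlation (with p) against the numeric covariates and a
    two-sided Wilcoxon rank-sum test across sex; a diagnostic that the model
    is not a surrogate for demographics or depth.  Constant covariates give
    NaN statistics.
    """
    meta = metadata.loc[scores.index]
    rows = []
    for cov in ("age", "depth"):
        v = meta[cov].to_numpy(dtype=float)
        if np.all(v == v[0]):
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(scores.to_numpy(), v)
        rows.append({"covariate": cov, "test": "spearman", "statistic": rho, "p": p})
    sex = meta["sex"].astype(str).to_numpy()
    levels = np.unique(sex)
    if len(levels) != 2:
        rows.append({"covariate": "sex", "test": "wilcoxon", "statistic": np.nan, "p": np.nan})
    else:
        a = scores.to_numpy()[sex == levels[0]]
        b = scores.to_numpy()[sex == levels[1]]
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"covariate": "sex", "test": "wilcoxon",
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
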