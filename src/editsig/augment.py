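"""Monte-Carlo tabular augmentation of the biomarker cohort.

Per class, biomarkers are mapped to the logit scale (clamped away from
0/1), summarised by their mean vector and a shrunk covariance, and new
points are multivariate-normal draws mapped back through the inverse
logit; binary covariates are Bernoulli draws at the class prevalence.
A fidelity report compares synthetic and original first/second moments
and correlation structure, and a fitted classifier's error on synthetic
points estimates prediction error.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta

from .constants import TREATMENT_CLASSES
from .rf import RFModel, encode_covariates, predict_votes, predicted_classes

#: clamp for proportions before the logit transform
CLAMP_EPS = 1e-4
#: maximum acceptable condition number of a shrunk class covariance
MAX_COND = 1e6


@dataclass
class MCGenerator:
    """Per-class moments of logit-scale biomarkers plus covariate laws."""

    classes: list
    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]
    gammas: dict[str, float]
    sex_prevalence: dict[str, float]
    treatment_prevalence: dict[str, dict[str, float]]
    class_weights: pd.Series
    feature_names: list
    seed: int = 0

    def digest(self) -> str:
        h = hashlib.sha256()
        for cls in self.classes:
            h.update(self.means[cls].tobytes())
            h.update(self.covs[cls].tobytes())
        h.update(self.class_weights.to_numpy().tobytes())
        return h.hexdigest()[:16]


def _clamped_logit(values: np.ndarray) -> np.ndarray:
    return logit(np.clip(values, CLAMP_EPS, 1 - CLAMP_EPS))


def _shrink(S: np.ndarray, grid_step: float = 0.05) -> tuple[np.ndarray, float]:
    """Smallest gamma with cond((1−γ)S + γ·diag(S)) <= MAX_COND."""
    D = np.diag(np.diag(S))
    for gamma in np.arange(0.0, 1.0 + grid_step / 2, grid_step):
        Sg = (1 - gamma) * S + gamma * D
        w = np.linalg.eigvalsh(Sg)
        if w.min() > 0 and w.max() / w.min() <= MAX_COND:
            return Sg, float(gamma)
    return D, 1.0


def fit_generator(matrix, cohort: pd.DataFrame, seed: int = 0) -> MCGenerator:
    """Fit the per-class generator from a biomarker matrix and cohort.

    Requires >= 5 samples per class.  Biomarker values are clamped to
    [1e-4, 1−1e-4] before the logit; each class covariance is shrunk
    toward its diagonal until well-conditioned.
    """
    df = matrix.values if hasattr(matrix, "meta") else matrix
    df = df.loc[cohort.index]
    y = cohort["diagnosis"]
    classes = list(dict.fromkeys(y))
    means, covs, gammas = {}, {}, {}
    sex_prev, treat_prev = {}, {}
    for cls in classes:
        sub = df[y == cls].dropna(axis=0, how="any")
        if len(sub) < 5:
            raise ValueError(f"class {cls!r} has fewer than 5 complete samples")
        Z = _clamped_logit(sub.to_numpy(dtype=float))
        means[cls] = Z.mean(axis=0)
        S = np.cov(Z, rowvar=False, ddof=1)
        covs[cls], gammas[cls] = _shrink(np.atleast_2d(S))
        csub = cohort[y == cls]
        sex_prev[cls] = float((csub["sex"] == "M").mean()) if "sex" in csub else 0.5
        treat_prev[cls] = {
            t: float(csub[t].mean()) if t in csub else 0.0 for t in TREATMENT_CLASSES
        }
    weights = y.value_counts(normalize=True).reindex(classes)
    return MCGenerator(
        classes=classes,
        means=means,
        covs=covs,
        gammas=gammas,
        sex_prevalence=sex_prev,
        treatment_prevalence=treat_prev,
        class_weights=weights,
        feature_names=list(df.columns),
        seed=seed,
    )


def largest_remainder(weights, n: int) -> np.ndarray:
    """Integer apportionment of n draws proportional to weights.

    Floors of the quotas are assigned first; leftover units go to the
    largest fractional remainders (ties to the earlier entry).
    Conserves n exactly.
    """
    w = np.asarray(weights, dtype=float)
    if n < 0:
        raise ValueError("n must be >= 0")
    quota = n * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n - counts.sum()
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


def sample_synthetic(
    gen: MCGenerator, n: int = 500, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw n synthetic samples from a fitted generator.

    Class counts follow largest-remainder apportionment of the class
    weights; biomarker draws are multivariate normal on the logit scale
    mapped back through the inverse logit (all values in (0, 1));
    covariates are Bernoulli at the class prevalence.

    Returns (biomarker matrix, cohort table).
    """
    if n < len(gen.classes):
        raise ValueError("n must be at least the number of classes")
    rng = np.random.default_rng(gen.seed if seed is None else seed)
    counts = largest_remainder(gen.class_weights.to_numpy(), n)
    mats, rows, ids = [], [], []
    i = 0
    for cls, k in zip(gen.classes, counts):
        if k == 0:
            continue
        Z = rng.multivariate_normal(gen.means[cls], gen.covs[cls], size=k, method="svd")
        mats.append(expit(Z))
        for _ in range(k):
            i += 1
            sid = f"MC{i:04d}"
            ids.append(sid)
            row = {
                "diagnosis": cls,
                "sex": "M" if rng.random() < gen.sex_prevalence[cls] else "F",
            }
            for t in TREATMENT_CLASSES:
                row[t] = int(rng.random() < gen.treatment_prevalence[cls][t])
            rows.append(row)
    matrix = pd.DataFrame(np.vstack(mats), index=ids, columns=gen.feature_names)
    cohort = pd.DataFrame(rows, index=ids)
    cohort.index.name = "sample"
    return matrix, cohort


def validate_synthetic(
    original: pd.DataFrame,
    original_labels,
    synthetic: pd.DataFrame,
    synthetic_labels,
    max_mean_shift: float = 0.3,
    sd_ratio_bounds: tuple[float, float] = (0.7, 1.4),
    max_corr_delta: float = 0.25,
) -> pd.DataFrame:
    """Fidelity report: per class and feature, moments and correlations.

    Columns: class, feature, mean_shift (|Δmean| in pooled-SD units),
    sd_ratio (synthetic/original), corr_delta (the class's max |Δ| of
    correlation matrices, repeated per feature) and pass flags against
    the thresholds.
    """
    if list(original.columns) != list(synthetic.columns):
        raise ValueError("original and synthetic schemas differ")
    y_o = pd.Series(original_labels, index=original.index)
    y_s = pd.Series(synthetic_labels, index=synthetic.index)
    rows = []
    for cls in dict.fromkeys(y_o):
        O = original[y_o == cls]
        S = synthetic[y_s == cls]
        if S.empty:
            raise ValueError(f"synthetic data has no samples for class {cls!r}")
        corr_delta = float(
            (O.corr() - S.corr()).abs().to_numpy()[
                ~np.eye(original.shape[1], dtype=bool)
            ].max()
        ) if original.shape[1] > 1 else 0.0
        for f in original.columns:
            mo, ms = O[f].mean(), S[f].mean()
            so, ss = O[f].std(ddof=1), S[f].std(ddof=1)
            pooled = np.sqrt((so**2 + ss**2) / 2)
            shift = abs(ms - mo) / pooled if pooled > 0 else 0.0
            ratio = ss / so if so > 0 else np.nan
            rows.append(
                {
                    "class": cls,
                    "feature": f,
                    "mean_shift": shift,
                    "sd_ratio": ratio,
                    "corr_delta": corr_delta,
                    "mean_pass": shift <= max_mean_shift,
                    "sd_pass": sd_ratio_bounds[0] <= ratio <= sd_ratio_bounds[1],
                    "corr_pass": corr_delta <= max_corr_delta,
                }
            )
    report = pd.DataFrame(rows)
    report["pass"] = report[["mean_pass", "sd_pass", "corr_pass"]].all(axis=1)
    return report


def estimate_prediction_error(
    model: RFModel, synthetic_matrix: pd.DataFrame, synthetic_cohort: pd.DataFrame
) -> pd.DataFrame:
    """Misclassification rate of a fitted model on synthetic points.

    Rows: 'overall' plus one per class, with the error rate, the count,
    and an exact (Clopper–Pearson) binomial 95% interval.
    """
    covs = encode_covariates(synthetic_cohort)
    features = synthetic_matrix.join(covs)
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"synthetic data missing model features: {missing}")
    votes = predict_votes(model, features)
    pred = predicted_classes(votes)
    truth = synthetic_cohort["diagnosis"]

    def _row(mask) -> dict:
        k = int((pred[mask] != truth[mask]).sum())
        m = int(mask.sum())
        lo = beta.ppf(0.025, k, m - k + 1) if k > 0 else 0.0
        hi = beta.ppf(0.975, k + 1, m - k) if k < m else 1.0
        return {"n": m, "error": k / m if m else np.nan, "ci_low": lo, "ci_high": hi}

    rows = {"overall": _row(pd.Series(True, index=truth.index))}
    for cls in dict.fromkeys(truth):
        rows[str(cls)] = _row(truth == cls)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out
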