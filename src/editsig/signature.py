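"""Per-comparison mROC virtual markers Z with ROC performance summaries.

For each pairwise diagnostic comparison, the selected (normalized)
biomarkers are combined into a virtual marker
``Z = a·biomarker1 + b·biomarker2 + …`` with Su–Liu coefficients, and
AUC, sensitivity, specificity, the decision cutoff (Youden's J), PPV
and NPV are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tei import mroc_coefficients

#: The six diagnostic comparisons, as (label, reference classes, case classes).
COMPARISONS = (
    ("Z1", ("CTRL",), ("BD",)),
    ("Z2", ("CTRL",), ("SZ", "SA")),
    ("Z3", ("BD",), ("SZ", "SA")),
    ("Z4", ("CTRL",), ("SZ",)),
    ("Z5", ("CTRL",), ("SA",)),
    ("Z6", ("SZ",), ("SA",)),
)


def empirical_auc(scores, labels) -> float:
    """Empirical ROC AUC: Mann–Whitney U / (n0·n1), ties at half credit.

    ``labels`` is boolean/0-1 with 1 = case (expected higher scores).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n0 * n1))


def auc_bruteforce(scores0, scores1) -> float:
    """Pair-enumeration AUC oracle (concordant pairs + half credit)."""
    s0 = np.asarray(scores0, dtype=float)
    s1 = np.asarray(scores1, dtype=float)
    wins = (s1[:, None] > s0[None, :]).sum()
    ties = (s1[:, None] == s0[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(s0) * len(s1)))


@dataclass
class Signature:
    """One comparison's virtual marker: coefficients and per-sample Z."""

    comparison: str
    ref_classes: tuple
    case_classes: tuple
    coefficients: pd.Series
    z: pd.Series  # all samples in the comparison
    labels: pd.Series  # 0 = reference, 1 = case
    z_all: pd.Series = None  # every sample projected on this axis


@dataclass
class RocSummary:
    """ROC summary at the Youden-optimal cutoff."""

    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    ppv: float
    npv: float
    prevalence: float


def ppv_npv(se: float, sp: float, prevalence: float) -> tuple[float, float]:
    """Predictive values from Se/Sp at prevalence pi (Bayes' rule)."""
    pi = prevalence
    ppv_den = se * pi + (1 - sp) * (1 - pi)
    npv_den = sp * (1 - pi) + (1 - se) * pi
    ppv = se * pi / ppv_den if ppv_den > 0 else np.nan
    npv = sp * (1 - pi) / npv_den if npv_den > 0 else np.nan
    return ppv, npv


def roc_metrics(z, labels, prevalence: float | None = None) -> RocSummary:
    """ROC summary with the cutoff maximizing Youden's J = Se + Sp − 1.

    A sample is called positive when ``z >= cutoff``; candidate cutoffs
    are the observed score values (ties broken toward the smaller
    cutoff).  PPV/NPV use ``prevalence`` (default: observed case
    fraction).
    """
    s = np.asarray(z, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    if np.unique(s).size < 2:
        raise ValueError("degenerate single-valued scores: cutoff undefined")
    auc = empirical_auc(s, y)
    n1, n0 = int(y.sum()), int((~y).sum())
    best = None
    for c in np.unique(s):
        se = float((s[y] >= c).mean())
        sp = float((s[~y] < c).mean())
        j = se + sp - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, c, se, sp)
    _, cutoff, se, sp = best
    pi = prevalence if prevalence is not None else n1 / (n0 + n1)
    ppv, npv = ppv_npv(se, sp, pi)
    return RocSummary(auc, se, sp, float(cutoff), ppv, npv, pi)


def fit_signature(values: pd.DataFrame, labels, comparison) -> Signature:
    """Fit one comparison's virtual marker on its two groups.

    ``comparison`` is a (label, ref classes, case classes) triple as in
    :data:`COMPARISONS`.  Coefficients come from the Su–Liu combination
    fitted on the comparison's two groups; Z is computed for every
    sample in the comparison.
    """
    name, ref_classes, case_classes = comparison
    y = pd.Series(labels, index=values.index) if not isinstance(labels, pd.Series) else labels
    in_ref = y.isin(ref_classes)
    in_case = y.isin(case_classes)
    if in_ref.sum() < 2 or in_case.sum() < 2:
        raise ValueError(f"comparison {name}: both groups need >= 2 samples")
    sub = values.loc[in_ref | in_case].dropna(axis=0, how="any")
    yb = in_case.loc[sub.index].astype(int)
    if len(sub) <= values.shape[1]:
        warnings.warn(
            f"comparison {name}: fewer samples than features; ridge path taken",
            stacklevel=2,
        )
    a = mroc_coefficients(
        sub.to_numpy()[yb.to_numpy() == 0], sub.to_numpy()[yb.to_numpy() == 1]
    )
    coef = pd.Series(a, index=values.columns, name=name)
    zscores = pd.Series(sub.to_numpy() @ a, index=sub.index, name=name)
    complete = values.dropna(axis=0, how="any")
    z_all = pd.Series(complete.to_numpy() @ a, index=complete.index, name=name)
    return Signature(
        name, tuple(ref_classes), tuple(case_classes), coef, zscores, yb, z_all
    )


def run_all_comparisons(
    values: pd.DataFrame, labels, prevalence: float | None = None
) -> tuple[dict[str, Signature], dict[str, RocSummary], pd.DataFrame]:
    """Fit Z1…Z6 and report a performance table.

    Returns (signatures, summaries, table); the table has one row per
    comparison with columns (comparison, groups, AUC, Se, Sp, cutoff,
    PPV, NPV).  Comparisons with an empty class are skipped with a
    warning.
    """
    y = pd.Series(labels, index=values.index) if not isinstance(labels, pd.Series) else labels
    signatures, summaries, rows = {}, {}, []
    for comparison in COMPARISONS:
        name, ref_classes, case_classes = comparison
        if not y.isin(ref_classes).any() or not y.isin(case_classes).any():
            warnings.warn(f"comparison {name} skipped: empty class", stacklevel=2)
            continue
        sig = fit_signature(values, y, comparison)
        roc = roc_metrics(sig.z.to_numpy(), sig.labels.to_numpy(), prevalence)
        signatures[name] = sig
        summaries[name] = roc
        rows.append(
            {
                "comparison": name,
                "groups": f"{'+'.join(ref_classes)} vs {'+'.join(case_classes)}",
                "AUC": roc.auc,
                "Se": roc.sensitivity,
                "Sp": roc.specificity,
                "cutoff": roc.cutoff,
                "PPV": roc.ppv,
                "NPV": roc.npv,
            }
        )
    return signatures, summaries, pd.DataFrame(rows)


def signature_coordinates(
    signatures: dict[str, Signature], triplet: tuple[str, str, str]
) -> pd.DataFrame:
    """Per-sample coordinates on three virtual markers (3-D scatter export).

    Every sample is projected on each axis with that comparison's
    coefficients, so points outside a comparison's two groups still get
    coordinates (as in a three-axis scatter of the whole cohort).
    """
    cols = {}
    for name in triplet:
        if name not in signatures:
            raise KeyError(f"signature {name!r} not fitted")
        cols[name] = signatures[name].z_all
    return pd.DataFrame(cols)
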