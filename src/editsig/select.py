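"""Feature selection: adaptive differential testing with BH FDR,
correlation pruning, Boruta shadow-feature selection and mutual
information.

The cascade reduces the candidate biomarkers to a significant,
non-redundant set: (1) keep biomarkers with raw p <= 0.05 in at least
one pairwise group comparison, (2) prune correlated features at
|r| > 0.6 (the member with the larger mean absolute correlation to all
other features is removed), (3) keep features the Boruta procedure
Confirms against permuted shadow copies; mutual information with the
class label is recorded for ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class FeatureSelectionConfig:
    """Thresholds and Boruta settings for the selection cascade."""

    corr_cutoff: float = 0.6
    raw_p_cutoff: float = 0.05
    fdr_cutoff: float = 0.1
    boruta_max_runs: int = 100
    boruta_alpha: float = 0.01
    boruta_trees: int = 100
    normality_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("corr_cutoff", "raw_p_cutoff", "fdr_cutoff", "boruta_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def differential_test(
    values_a,
    values_b,
    config: FeatureSelectionConfig | None = None,
    force: str | None = None,
) -> tuple[str, float]:
    """Two-group test chosen adaptively from normality and variance.

    Shapiro–Wilk per group (alpha 0.05); both normal -> F-test for
    variance equality -> Student's t (equal) or Welch's t (unequal);
    otherwise two-sided Mann–Whitney with tie correction.  ``force``
    overrides the choice ('mann-whitney', 'student-t' or 'welch-t').

    Returns (test name, raw two-sided p).
    """
    config = config or FeatureSelectionConfig()
    a = np.asarray(pd.Series(values_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(values_b).dropna(), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 non-missing values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn("constant values in both groups; p set to 1", stacklevel=2)
        return "mann-whitney", 1.0

    if force is None:
        alpha = config.normality_alpha
        normal = True
        for g in (a, b):
            if np.ptp(g) == 0:
                normal = False
                break
            if stats.shapiro(g).pvalue <= alpha:
                normal = False
                break
        if normal:
            f = np.var(a, ddof=1) / np.var(b, ddof=1)
            dfa, dfb = len(a) - 1, len(b) - 1
            p_var = 2 * min(
                stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb)
            )
            force = "student-t" if p_var > alpha else "welch-t"
        else:
            force = "mann-whitney"

    if force == "student-t":
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
    elif force == "welch-t":
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif force == "mann-whitney":
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test {force!r}")
    return force, float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def find_correlated(corr: pd.DataFrame, cutoff: float = 0.6) -> list:
    """Features to remove given an absolute-correlation matrix.

    Pairs above the cutoff are scanned in row-major order; the member
    with the larger mean absolute correlation to all other features is
    flagged (ties remove the later column).  Flagged features are
    ignored in later pairs.
    """
    A = corr.abs()
    cols = list(A.columns)
    n = len(cols)
    mean_abs = (A.to_numpy().sum(axis=0) - np.diag(A.to_numpy())) / max(n - 1, 1)
    flagged: set[int] = set()
    for i in range(n):
        if i in flagged:
            continue
        for j in range(i + 1, n):
            if j in flagged or i in flagged:
                continue
            if A.iat[i, j] > cutoff:
                drop = i if mean_abs[i] > mean_abs[j] else j
                flagged.add(drop)
    return [cols[k] for k in sorted(flagged)]


def correlation_filter(
    matrix: pd.DataFrame, cutoff: float = 0.6
) -> tuple[list, list]:
    """Prune features correlated above ``cutoff`` (absolute Pearson).

    Zero-variance features get correlation 0 with everything (retained,
    with a warning).  Returns (kept ids, removed ids) in column order.
    """
    if matrix.shape[1] < 2 or matrix.dropna().shape[0] < 3:
        raise ValueError("need >= 2 features and >= 3 complete samples")
    zero_var = matrix.std(ddof=1) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance features retained: {list(matrix.columns[zero_var])}",
            stacklevel=2,
        )
    corr = matrix.corr(method="pearson").fillna(0.0)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    removed = find_correlated(corr, cutoff)
    kept = [c for c in matrix.columns if c not in removed]
    return kept, removed


@dataclass
class BorutaResult:
    """Per-feature Boruta decisions with hit counts.

    ``decisions`` is indexed by feature with columns decision
    (Confirmed/Tentative/Rejected), hits and runs.
    """

    decisions: pd.DataFrame
    runs: int

    @property
    def confirmed(self) -> list:
        d = self.decisions
        return list(d.index[d["decision"] == "Confirmed"])


def boruta_select(
    matrix: pd.DataFrame,
    labels,
    config: FeatureSelectionConfig | None = None,
) -> BorutaResult:
    """Boruta all-relevant selection against permuted shadow features.

    Per run, every undecided feature gets one permuted shadow copy; a
    random forest is fitted and a feature scores a hit when its
    permutation importance (accuracy drop on an internal held-out
    split) exceeds the maximum shadow importance.  Hits are tested
    against Binomial(runs, 0.5) two-sided with Holm step-down
    correction at ``boruta_alpha``; features undecided after
    ``boruta_max_runs`` stay Tentative.
    """
    config = config or FeatureSelectionConfig()
    y = pd.Series(labels).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("Boruta needs >= 2 classes")
    if matrix.shape[1] < 1:
        raise ValueError("Boruta needs >= 1 feature")
    X = matrix.to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmedian(X, axis=0), X)
    features = list(matrix.columns)
    rng = np.random.default_rng(config.seed)

    hits = dict.fromkeys(features, 0)
    runs_of = dict.fromkeys(features, 0)
    decision = dict.fromkeys(features, "Tentative")
    undecided = list(features)

    for run in range(1, config.boruta_max_runs + 1):
        idx = [features.index(f) for f in undecided]
        Xr = X[:, idx]
        shadow = Xr.copy()
        for j in range(shadow.shape[1]):
            shadow[:, j] = rng.permutation(shadow[:, j])
        Xall = np.hstack([Xr, shadow])
        seed_run = int(rng.integers(0, 2**31 - 1))
        Xtr, Xte, ytr, yte = train_test_split(
            Xall, y, test_size=0.3, stratify=y, random_state=seed_run
        )
        forest = RandomForestClassifier(
            n_estimators=config.boruta_trees,
            min_samples_leaf=1,
            random_state=seed_run,
            n_jobs=1,
        ).fit(Xtr, ytr)
        imp = permutation_importance(
            forest, Xte, yte, n_repeats=1, random_state=seed_run, n_jobs=1
        ).importances_mean
        real_imp = imp[: len(undecided)]
        shadow_max = imp[len(undecided):].max()
        for f, v in zip(undecided, real_imp):
            runs_of[f] += 1
            if v > shadow_max:
                hits[f] += 1

        # Holm step-down over the undecided features
        pvals = {
            f: stats.binomtest(hits[f], runs_of[f], 0.5).pvalue for f in undecided
        }
        order = sorted(undecided, key=lambda f: pvals[f])
        m = len(order)
        significant: set = set()
        for rank, f in enumerate(order):
            if pvals[f] <= config.boruta_alpha / (m - rank):
                significant.add(f)
            else:
                break
        for f in significant:
            decision[f] = (
                "Confirmed" if hits[f] / runs_of[f] > 0.5 else "Rejected"
            )
        undecided = [f for f in undecided if decision[f] == "Tentative"]
        if not undecided:
            break

    table = pd.DataFrame(
        {
            "decision": [decision[f] for f in features],
            "hits": [hits[f] for f in features],
            "runs": [runs_of[f] for f in features],
        },
        index=pd.Index(features, name="feature"),
    )
    return BorutaResult(table, run)


def mutual_information(values, labels, bins: int | None = None) -> float:
    """Plug-in mutual information (nats) of a binned feature vs class.

    Equal-frequency discretization into ceil(n^(1/3)) bins by default.
    Returns 0 for a single-class label vector.
    """
    x = pd.Series(values).reset_index(drop=True)
    y = pd.Series(labels).reset_index(drop=True)
    keep = x.notna()
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 10:
        raise ValueError("mutual information needs n >= 10")
    if y.nunique() < 2:
        return 0.0
    k = bins or int(np.ceil(n ** (1 / 3)))
    binned = pd.qcut(x.rank(method="first"), q=min(k, x.nunique()), labels=False)
    joint = pd.crosstab(binned, y).to_numpy(dtype=float)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px @ py))
    return float(np.nansum(terms))


@dataclass
class FeatureSelectionResult:
    """Outcome of the full cascade plus a per-stage audit table."""

    selected: list
    report: pd.DataFrame
    boruta: BorutaResult
    per_gene_counts: pd.Series = field(default=None)


def select_features(
    matrix,
    labels,
    config: FeatureSelectionConfig | None = None,
    gene_of: pd.Series | None = None,
) -> FeatureSelectionResult:
    """Run the cascade: p-filter -> correlation pruning -> Boruta.

    ``matrix`` is a samples x features DataFrame (or a BiomarkerMatrix,
    whose metadata then supplies the per-gene counts).  A feature passes
    the p-filter when any pairwise group comparison has raw
    p <= ``raw_p_cutoff``.  Mutual information with the class label is
    recorded for ranking only.  Raises if any stage empties the list,
    naming the stage.
    """
    config = config or FeatureSelectionConfig()
    if hasattr(matrix, "values") and hasattr(matrix, "meta"):
        gene_of = matrix.meta["gene"]
        df = matrix.values
    else:
        df = matrix
    y = pd.Series(labels, index=df.index) if not isinstance(labels, pd.Series) else labels
    groups = sorted(y.unique())

    rows = {}
    for f in df.columns:
        best_p, best_test = 1.0, None
        for g1, g2 in combinations(groups, 2):
            a = df.loc[y == g1, f]
            b = df.loc[y == g2, f]
            if a.notna().sum() < 3 or b.notna().sum() < 3:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                test, p = differential_test(a, b, config)
            if p < best_p:
                best_p, best_test = p, test
        rows[f] = {"test": best_test, "p": best_p}
    report = pd.DataFrame.from_dict(rows, orient="index")
    report.index.name = "biomarker"
    report["fdr"] = bh_adjust(report["p"].to_numpy())

    passed_p = list(report.index[report["p"] <= config.raw_p_cutoff])
    if not passed_p:
        raise ValueError("selection emptied at stage: p-filter")

    if len(passed_p) >= 2:
        kept_corr, removed_corr = correlation_filter(df[passed_p], config.corr_cutoff)
    else:
        kept_corr, removed_corr = passed_p, []
    report["kept_after_corr"] = report.index.isin(kept_corr)
    if not kept_corr:
        raise ValueError("selection emptied at stage: correlation-filter")

    boruta = boruta_select(df[kept_corr], y, config)
    report["boruta_decision"] = ""
    report.loc[boruta.decisions.index, "boruta_decision"] = boruta.decisions["decision"]
    selected = boruta.confirmed
    if not selected:
        raise ValueError("selection emptied at stage: boruta")

    report["mi"] = np.nan
    for f in selected:
        report.loc[f, "mi"] = mutual_information(df[f], y)

    per_gene = None
    if gene_of is not None:
        per_gene = (
            pd.Series({f: gene_of[f] for f in selected}).value_counts().sort_index()
        )
        logger.info("selected biomarkers per gene: %s", per_gene.to_dict())
    return FeatureSelectionResult(selected, report, boruta, per_gene)
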