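"""Target Editing Index: per-gene AUC-maximizing combination of variants.

The TEI summarises a gene's significant editing variants as a single
scalar via the Su–Liu optimal linear combination — the direction
``a ∝ (S_ref + S_case)^{-1} (mu_case − mu_ref)`` that maximises the ROC
AUC of a linear score under (near-)Gaussian marker distributions — then
applies a Box-Cox transform so downstream group tests act on roughly
normal values.  The Box-Cox map is strictly monotone, so rank-based
statistics (Mann–Whitney, empirical AUC) are unchanged by it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DIAGNOSES
from .select import FeatureSelectionConfig, bh_adjust, differential_test

logger = logging.getLogger(__name__)


def mroc_coefficients(X_ref, X_case, ridge: float | None = None) -> np.ndarray:
    """Su–Liu optimal linear-combination coefficients (unit L2 norm).

    ``a ∝ (S_ref + S_case)^{-1} (mu_case − mu_ref)`` with sample means
    and covariances; a ridge ``eps·I`` (eps = 1e-6·trace(S)/p by
    default) is added when the pooled covariance sum is
    ill-conditioned.  Orientation: the case-group mean score is >= the
    reference-group mean score on the fit data.
    """
    Xr = np.atleast_2d(np.asarray(X_ref, dtype=float))
    Xc = np.atleast_2d(np.asarray(X_case, dtype=float))
    if Xr.ndim != 2 or Xc.ndim != 2 or Xr.shape[1] != Xc.shape[1]:
        raise ValueError("reference and case blocks must share the feature axis")
    if Xr.shape[0] < 2 or Xc.shape[0] < 2:
        raise ValueError("need >= 2 samples per group")
    p = Xr.shape[1]
    delta = Xc.mean(axis=0) - Xr.mean(axis=0)
    if p == 1:
        return np.array([1.0])
    S = np.cov(Xr, rowvar=False) + np.cov(Xc, rowvar=False)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e8:
        eps = ridge if ridge is not None else 1e-6 * np.trace(S) / p
        S = S + eps * np.eye(p)
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"covariance sum singular after ridge (condition number {cond:.3g})"
            )
    a = np.linalg.solve(S, delta)
    norm = np.linalg.norm(a)
    if norm == 0:
        # identical group means: any unit direction is AUC-neutral
        a = np.zeros(p)
        a[0] = 1.0
        return a
    a = a / norm
    if (Xc @ a).mean() < (Xr @ a).mean():
        a = -a
    return a


@dataclass
class BoxcoxParams:
    """Fitted Box-Cox parameters: exponent lambda and positivity shift."""

    lam: float
    shift: float


def boxcox_transform(values, grid_step: float = 0.01) -> tuple[BoxcoxParams, np.ndarray]:
    """Box-Cox transform with profile-likelihood lambda on [-2, 2].

    Inputs are shifted by ``max(0, 1e-6 − min(values))`` so all are
    positive; lambda is chosen by a profile log-likelihood grid search
    (step 0.01); the transform is ``(x**lam − 1)/lam`` (log at lam=0).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(np.unique(x)) < 5:
        raise ValueError("Box-Cox needs >= 5 distinct values")
    shift = max(0.0, 1e-6 - x.min())
    xs = x + shift
    grid = np.arange(-2.0, 2.0 + grid_step / 2, grid_step)
    lls = [stats.boxcox_llf(lam, xs) for lam in grid]
    lam = float(grid[int(np.argmax(lls))])
    return BoxcoxParams(lam, shift), apply_boxcox(values, BoxcoxParams(lam, shift))


def apply_boxcox(values, params: BoxcoxParams) -> np.ndarray:
    x = np.asarray(values, dtype=float) + params.shift
    if abs(params.lam) < 1e-12:
        return np.log(x)
    return (x**params.lam - 1.0) / params.lam


@dataclass
class TEIResult:
    """Per-gene TEI fit: coefficients, Box-Cox parameters and values."""

    coefficients: dict[str, pd.Series]
    boxcox: dict[str, BoxcoxParams]
    tei: pd.DataFrame  # samples x genes
    scaling: dict[str, tuple[pd.Series, pd.Series]]  # per gene: (mean, sd)


def compute_tei(
    matrix,
    labels,
    selected: dict[str, list[str]],
    reference: str = "CTRL",
) -> TEIResult:
    """Per-gene TEI for all samples.

    For each gene with >= 1 selected variant the variants are
    standardized (z-scored), Su–Liu coefficients are fitted on
    ``reference`` vs all other samples, the linear score is Box-Cox
    transformed, and the transformed TEI is returned for every sample.
    Genes without selected variants are skipped with a warning.
    """
    df = matrix.values if hasattr(matrix, "meta") else matrix
    y = pd.Series(labels, index=df.index) if not isinstance(labels, pd.Series) else labels
    is_ref = (y == reference).to_numpy()
    if is_ref.sum() < 2 or (~is_ref).sum() < 2:
        raise ValueError("need >= 2 reference and >= 2 case samples")

    coefs, bparams, scalings, cols = {}, {}, {}, {}
    for gene, variants in selected.items():
        if not variants:
            warnings.warn(f"gene {gene!r} has no selected variants; skipped", stacklevel=2)
            continue
        sub = df[variants]
        mean, sd = sub.mean(), sub.std(ddof=1).replace(0, 1.0)
        z = (sub - mean) / sd
        complete = z.notna().all(axis=1).to_numpy()
        a = mroc_coefficients(
            z.to_numpy()[complete & is_ref], z.to_numpy()[complete & ~is_ref]
        )
        raw = z.to_numpy() @ a
        params, transformed = boxcox_transform(raw)
        out = np.full(len(df), np.nan)
        out[~np.isnan(raw)] = apply_boxcox(raw[~np.isnan(raw)], params)
        coefs[gene] = pd.Series(a, index=variants)
        bparams[gene] = params
        scalings[gene] = (mean, sd)
        cols[gene] = out
    if not cols:
        raise ValueError("no gene had selected variants")
    tei = pd.DataFrame(cols, index=df.index)
    return TEIResult(coefs, bparams, tei, scalings)


def tei_group_tests(
    tei: pd.DataFrame,
    labels,
    fdr_cutoff: float = 0.10,
    config: FeatureSelectionConfig | None = None,
) -> pd.DataFrame:
    """Six pairwise group comparisons per gene with BH FDR within each.

    Returns a long table (comparison, gene, test, p, fdr, significant)
    with exactly one row per (comparison, gene); missing groups are
    omitted with a warning.  Significance is flagged at
    FDR < ``fdr_cutoff``.
    """
    y = pd.Series(labels, index=tei.index) if not isinstance(labels, pd.Series) else labels
    present = [d for d in DIAGNOSES if (y == d).sum() >= 3]
    skipped = [d for d in DIAGNOSES if d in set(y.unique()) and d not in present]
    for d in set(y.unique()) - set(DIAGNOSES):
        present.append(d)
    if skipped:
        warnings.warn(f"groups with < 3 samples omitted: {skipped}", stacklevel=2)

    rows = []
    for g1, g2 in combinations(present, 2):
        comp = f"{g1}|{g2}"
        ps, tests = [], []
        for gene in tei.columns:
            a = tei.loc[y == g1, gene]
            b = tei.loc[y == g2, gene]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                test, p = differential_test(a, b, config)
            ps.append(p)
            tests.append(test)
        fdr = bh_adjust(ps)
        for gene, test, p, q in zip(tei.columns, tests, ps, fdr):
            rows.append(
                {
                    "comparison": comp,
                    "gene": gene,
                    "test": test,
                    "p": p,
                    "fdr": q,
                    "significant": q < fdr_cutoff,
                }
            )
    return pd.DataFrame(rows)
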