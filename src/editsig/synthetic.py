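"""Seeded synthetic cohorts with the structure the analysis assumes.

Per-site editing proportions follow a logistic-normal model: a
correlated Gaussian vector on the logit scale (per-class mean shifts,
per-gene correlation blocks) mapped through the inverse logit, then
observed through beta-binomial read noise at a configurable depth.
Covariates (sex, five psychotropic-treatment flags, age) are sampled
independently per diagnostic class from the cohort's marginal
prevalences.  Everything is fully determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .constants import DIAGNOSES, GENES, TREATMENT_CLASSES
from .panel import ALT_BASE, REF_BASE, SitePanel, default_panel
from .quant import BASE_CODE, BASES, BiomarkerMatrix

#: clamp for proportions before/after logit, avoiding +-inf
LOGIT_EPS = 1e-4

# Table-style cohort margins the generator emulates by default:
# class sizes, male fraction, per-treatment fraction and age moments of
# the study population (169 subjects across 4 diagnostic groups).
_CLASS_SIZES = {"CTRL": 85, "BD": 39, "SZ": 31, "SA": 14}
_MALE = {"CTRL": 47 / 85, "BD": 11 / 39, "SZ": 23 / 31, "SA": 10 / 14}
_TREATMENT = {
    "CTRL": dict.fromkeys(TREATMENT_CLASSES, 0.0),
    "SZ": {
        "antipsychotics": 29 / 31,
        "antidepressants": 18 / 31,
        "anxiolytics": 5 / 31,
        "antiepileptics": 12 / 31,
        "hypnotics_sedatives": 1 / 31,
    },
    "SA": {
        "antipsychotics": 14 / 14,
        "antidepressants": 8 / 14,
        "anxiolytics": 2 / 14,
        "antiepileptics": 5 / 14,
        "hypnotics_sedatives": 0.0,
    },
    "BD": {
        "antipsychotics": 28 / 39,
        "antidepressants": 5 / 39,
        "anxiolytics": 0.0,
        "antiepileptics": 26 / 39,
        "hypnotics_sedatives": 0.0,
    },
}
_AGE = {"CTRL": (40.3, 11.2), "SZ": (42.8, 9.8), "SA": (45.6, 6.7), "BD": (44.7, 9.7)}
_AGE_BOUNDS = (18.0, 65.0)

# Default per-class editing effects (logit shifts), chosen to emulate the
# qualitative group structure of the cohort: the BD group differs on
# seven genes, SZ on KCNJ15/PRKCB and SA on KCNJ15/LYN relative to
# controls.  Effect sizes are calibration choices (see docs/methods.md),
# not measured values.
_DEFAULT_SHIFT = 1.2
_AFFECTED_GENES = {
    "BD": ("CAMK1D", "GAB2", "IFNAR1", "KCNJ15", "LYN", "MDM2", "PDE8A"),
    "SZ": ("KCNJ15", "PRKCB"),
    "SA": ("KCNJ15", "LYN"),
}
_SITES_PER_EFFECT = 2

#: baseline editing proportions cycled over a gene's sites
_BASELINE_CYCLE = (0.03, 0.08, 0.15, 0.25, 0.06, 0.12, 0.20, 0.10)


@dataclass
class SyntheticCohortSpec:
    """Full parameterization of a synthetic cohort.

    Editing proportions live on the logit scale: per-site baseline means,
    a unit-diagonal correlation matrix (per-gene blocks by default), a
    per-site latent SD (``site_scale``) and per-(class, site) logit
    shifts.  ``overdispersion`` is the beta-binomial concentration of
    read-level noise around the latent proportion.
    """

    class_sizes: dict[str, int]
    site_panel: SitePanel
    baseline_logit_means: pd.Series
    site_correlation: pd.DataFrame
    site_scale: pd.Series
    group_effects: dict[tuple[str, str], float]
    overdispersion: pd.Series
    sex_prevalence: dict[str, float]
    treatment_prevalence: dict[tuple[str, str], float]
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_AGE)
    )
    reads_per_sample: int = 10_000
    seq_error: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        sites = self.site_panel.site_ids
        if any(n < 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be >= 0")
        for name, series in (
            ("baseline_logit_means", self.baseline_logit_means),
            ("site_scale", self.site_scale),
            ("overdispersion", self.overdispersion),
        ):
            if list(series.index) != sites:
                raise ValueError(f"{name} must be indexed by the panel's site ids")
        if (self.site_scale <= 0).any() or (self.overdispersion <= 0).any():
            raise ValueError("site_scale and overdispersion must be > 0")
        C = self.site_correlation
        if list(C.index) != sites or list(C.columns) != sites:
            raise ValueError("site_correlation must be indexed by the panel's site ids")
        A = C.to_numpy()
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("site_correlation must be symmetric")
        if not np.allclose(np.diag(A), 1.0, atol=1e-10):
            raise ValueError("site_correlation must have unit diagonal")
        w = np.linalg.eigvalsh(A)
        if w.min() < -1e-8:
            raise ValueError(
                f"site_correlation is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})"
            )
        for d, p in self.sex_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sex prevalence out of [0,1] for {d}")
        for key, p in self.treatment_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"treatment prevalence out of [0,1] for {key}")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if not 0.0 <= self.seq_error < 1.0:
            raise ValueError("seq_error must be in [0, 1)")

    @property
    def diagnoses(self) -> list[str]:
        return [d for d in DIAGNOSES if d in self.class_sizes] + [
            d for d in self.class_sizes if d not in DIAGNOSES
        ]

    def with_seed(self, seed: int) -> "SyntheticCohortSpec":
        return replace(self, seed=seed)

    def class_mean(self, diagnosis: str) -> pd.Series:
        """Latent logit mean vector for one class (baseline + shifts)."""
        mu = self.baseline_logit_means.copy()
        for (d, site), shift in self.group_effects.items():
            if d == diagnosis:
                mu[site] += shift
        return mu


def _block_correlation(panel: SitePanel, within_gene_r: float) -> pd.DataFrame:
    sites = panel.sites
    ids = list(sites["site"])
    genes = sites["gene"].to_numpy()
    same_gene = genes[:, None] == genes[None, :]
    A = np.where(same_gene, within_gene_r, 0.0)
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=ids, columns=ids)


def spec_from_table1(
    panel: SitePanel | None = None,
    effect_shift: float = _DEFAULT_SHIFT,
    within_gene_r: float = 0.3,
    site_scale: float = 0.6,
    overdispersion: float = 300.0,
    seed: int = 0,
) -> SyntheticCohortSpec:
    """Default synthetic-cohort spec emulating the study population.

    Class sizes CTRL=85, BD=39, SZ=31, SA=14 and the per-class sex,
    treatment and age margins reproduce the published cohort table;
    editing effect sizes and the latent covariance are documented
    calibration defaults.
    """
    panel = panel or default_panel()
    sites = panel.sites
    baseline = pd.Series(
        [
            logit(_BASELINE_CYCLE[k % len(_BASELINE_CYCLE)])
            for gene in panel.genes
            for k in range(len(panel.gene_sites(gene)))
        ],
        index=list(sites["site"]),
        dtype=float,
    )
    effects: dict[tuple[str, str], float] = {}
    for diag, genes in _AFFECTED_GENES.items():
        for gene in genes:
            gsites = panel.gene_sites(gene)["site"]
            for site in gsites[:_SITES_PER_EFFECT]:
                effects[(diag, site)] = effect_shift
    return SyntheticCohortSpec(
        class_sizes=dict(_CLASS_SIZES),
        site_panel=panel,
        baseline_logit_means=baseline,
        site_correlation=_block_correlation(panel, within_gene_r),
        site_scale=pd.Series(site_scale, index=list(sites["site"]), dtype=float),
        group_effects=effects,
        overdispersion=pd.Series(overdispersion, index=list(sites["site"]), dtype=float),
        sex_prevalence=dict(_MALE),
        treatment_prevalence={
            (d, t): _TREATMENT[d][t] for d in _CLASS_SIZES for t in TREATMENT_CLASSES
        },
        seed=seed,
    )


def _latent_proportions(
    spec: SyntheticCohortSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-sample latent editing proportions and diagnosis labels."""
    sites = spec.site_panel.site_ids
    scale = spec.site_scale.to_numpy()
    cov = spec.site_correlation.to_numpy() * np.outer(scale, scale)
    chunks, labels = [], []
    for diag in spec.diagnoses:
        n = spec.class_sizes[diag]
        if n == 0:
            continue
        mu = spec.class_mean(diag).to_numpy()
        z = rng.multivariate_normal(mu, cov, size=n, method="svd")
        chunks.append(expit(z))
        labels.extend([diag] * n)
    p = np.clip(np.vstack(chunks), LOGIT_EPS, 1 - LOGIT_EPS)
    ids = [f"S{i:04d}" for i in range(1, len(labels) + 1)]
    return (
        pd.DataFrame(p, index=ids, columns=sites),
        pd.Series(labels, index=ids, name="diagnosis"),
    )


def _sample_covariates(
    spec: SyntheticCohortSpec, labels: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    lo, hi = _AGE_BOUNDS
    rows = {}
    for sample, diag in labels.items():
        male = rng.random() < spec.sex_prevalence[diag]
        mean, sd = spec.age_mean_sd[diag]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        age = float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
        row = {"diagnosis": diag, "sex": "M" if male else "F", "age": round(age, 1)}
        for t in TREATMENT_CLASSES:
            row[t] = int(rng.random() < spec.treatment_prevalence.get((diag, t), 0.0))
        rows[sample] = row
    cohort = pd.DataFrame.from_dict(rows, orient="index")
    cohort.index.name = "sample"
    return cohort


def generate_cohort(
    spec: SyntheticCohortSpec, return_latent: bool = False
) -> tuple[BiomarkerMatrix, pd.DataFrame]:
    """Generate a (biomarker matrix, cohort table) pair from a spec.

    Observed site values are beta-binomial draws at
    ``spec.reads_per_sample`` depth around the latent logistic-normal
    proportion.  With ``return_latent=True`` the latent per-sample
    proportions are returned as a third element.
    """
    rng = np.random.default_rng(spec.seed)
    p, labels = _latent_proportions(spec, rng)
    kappa = spec.overdispersion.to_numpy()
    a = p.to_numpy() * kappa
    b = (1 - p.to_numpy()) * kappa
    theta = rng.beta(a, b)
    edited = rng.binomial(spec.reads_per_sample, theta)
    values = pd.DataFrame(
        edited / spec.reads_per_sample, index=p.index, columns=p.columns
    )
    site_gene = spec.site_panel.sites.set_index("site")["gene"]
    meta = pd.DataFrame(
        {
            "gene": [site_gene[s] for s in values.columns],
            "kind": "site",
            "sites": list(values.columns),
        },
        index=values.columns,
    )
    meta.index.name = "biomarker"
    matrix = BiomarkerMatrix(values, meta)
    cohort = _sample_covariates(spec, labels, rng)
    if return_latent:
        return matrix, cohort, p
    return matrix, cohort


@dataclass
class AlignedReadSet:
    """Aligned reads of one sample, one call per panel site.

    ``calls`` maps gene -> (n_reads, n_sites) uint8 array of base codes
    (index into "ACGTN"), sites in panel positional order.
    """

    sample_id: str
    calls: dict[str, np.ndarray]

    @property
    def n_reads(self) -> int:
        return int(sum(c.shape[0] for c in self.calls.values()))


def generate_reads(
    spec: SyntheticCohortSpec,
    sample_editing: pd.Series,
    sample_id: str = "sample",
    seed: int | None = None,
) -> AlignedReadSet:
    """Simulate phased aligned reads for one sample.

    Each read carries a jointly sampled editing pattern over its gene's
    sites (sites independent given the per-site proportions); an edited
    position reads as G on the + strand and C on the − strand.
    Sequencing error substitutes a uniformly random other base with
    probability ``spec.seq_error`` per call.  ``spec.reads_per_sample``
    reads are generated per gene.
    """
    panel = spec.site_panel
    unknown = set(sample_editing.index) - set(panel.site_ids)
    if unknown:
        raise ValueError(f"sites not in panel: {sorted(unknown)[:5]}")
    if ((sample_editing < 0) | (sample_editing > 1)).any():
        raise ValueError("editing proportions must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    m = spec.reads_per_sample
    # replacement table: for a true base code, the 3 possible error bases
    others = np.array(
        [[BASE_CODE[b] for b in BASES[:4] if b != t] for t in BASES[:4]], dtype=np.uint8
    )
    calls: dict[str, np.ndarray] = {}
    for gene in panel.genes:
        gsites = panel.gene_sites(gene)
        site_ids = [s for s in gsites["site"] if s in sample_editing.index]
        if not site_ids:
            continue
        sub = gsites[gsites["site"].isin(site_ids)]
        p = sample_editing[list(sub["site"])].to_numpy()
        ref = sub["ref_base"].map(BASE_CODE).to_numpy(dtype=np.uint8)
        alt = sub["strand"].map(ALT_BASE).map(BASE_CODE).to_numpy(dtype=np.uint8)
        edited = rng.random((m, len(p))) < p
        base = np.where(edited, alt, ref).astype(np.uint8)
        if spec.seq_error > 0:
            err = rng.random(base.shape) < spec.seq_error
            n_err = int(err.sum())
            if n_err:
                pick = rng.integers(0, 3, size=n_err)
                base[err] = others[base[err], pick]
        calls[gene] = base
    return AlignedReadSet(sample_id, calls)


def write_sam(readset: AlignedReadSet, panel: SitePanel, path: str | Path) -> None:
    """Write a read set as SAM with minimal @HD/@SQ headers.

    Each gene is a reference contig; reads span the gene's panel sites
    with the reference base at non-panel filler positions.
    """
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    spans = {}
    for gene in panel.genes:
        gsites = panel.gene_sites(gene)
        lo, hi = int(gsites["position"].min()), int(gsites["position"].max())
        spans[gene] = (lo, hi, gsites)
        lines.append(f"@SQ\tSN:{gene}\tLN:{hi + 10}")
    for gene, codes in readset.calls.items():
        lo, hi, gsites = spans[gene]
        offsets = (gsites["position"] - lo).to_numpy()
        length = hi - lo + 1
        filler = np.full(length, "A", dtype="U1")
        for off, rb in zip(offsets, gsites["ref_base"]):
            filler[off] = rb
        cigar = f"{length}M"
        base_chars = np.array(list(BASES), dtype="U1")
        for i in range(codes.shape[0]):
            seq = filler.copy()
            seq[offsets] = base_chars[codes[i]]
            lines.append(
                f"{readset.sample_id}.{gene}.r{i}\t0\t{gene}\t{lo + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{''.join(seq)}\t*"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sam(path: str | Path, panel: SitePanel, sample_id: str) -> AlignedReadSet:
    """Read panel-site base calls from a SAM file (via pysam)."""
    import pysam

    per_gene: dict[str, list[np.ndarray]] = {g: [] for g in panel.genes}
    positions = {g: panel.gene_sites(g)["position"].to_numpy() for g in panel.genes}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.reference_name not in per_gene:
                continue
            gene = read.reference_name
            seq = read.query_sequence
            ref2query = {r: q for q, r in read.get_aligned_pairs(matches_only=True)}
            row = np.full(len(positions[gene]), BASE_CODE["N"], dtype=np.uint8)
            for j, pos in enumerate(positions[gene]):
                q = ref2query.get(int(pos))
                if q is not None:
                    row[j] = BASE_CODE.get(seq[q].upper(), BASE_CODE["N"])
            per_gene[gene].append(row)
    calls = {
        g: np.vstack(rows) for g, rows in per_gene.items() if rows
    }
    return AlignedReadSet(sample_id, calls)


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=True)


def write_matrix_tsv(matrix: BiomarkerMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index=True, index_label="sample")
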