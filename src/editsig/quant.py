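"""Editing quantification: site, isoform and motif biomarkers from reads.

Editing at a site is the fraction of edited base calls among
(reference + edited) calls: G/(A+G) on the + strand, C/(T+C) on the −
strand; other bases are excluded from the denominator.  Isoform
biomarkers are per-read joint editing patterns over a gene's sites;
motif biomarkers aggregate a declared group of sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ALT_BASE, SitePanel

logger = logging.getLogger(__name__)

#: base alphabet used by integer-coded read calls.
BASES = "ACGTN"
BASE_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class QCConfig:
    """Quality-control thresholds for editing quantification.

    min_sample_depth: minimum total aligned reads per sample; samples
        below it are flagged failed-QC and all their values are missing.
    min_site_depth: minimum (reference+edited) calls for a per-site
        fraction to be reported.
    background_threshold: biomarkers whose cohort median falls below
        this are treated as background and dropped.
    """

    min_sample_depth: int = 10_000
    min_site_depth: int = 50
    background_threshold: float = 0.005

    def __post_init__(self) -> None:
        if self.min_sample_depth <= 0 or self.min_site_depth <= 0:
            raise ValueError("QC depth thresholds must be > 0")
        if self.background_threshold < 0:
            raise ValueError("background_threshold must be >= 0")


@dataclass
class SiteEditingTable:
    """Per-(sample, site) editing counts and fractions.

    ``table`` columns: sample, gene, site, edited, reference, depth,
    fraction (NaN when depth < min_site_depth or the sample failed QC).
    """

    table: pd.DataFrame
    sample_depth: pd.Series
    failed_samples: list[str] = field(default_factory=list)

    def fractions(self) -> pd.DataFrame:
        """Samples x sites matrix of editing fractions."""
        return self.table.pivot(index="sample", columns="site", values="fraction")


@dataclass
class BiomarkerMatrix:
    """Samples x biomarkers editing values with biomarker metadata.

    ``meta`` is indexed by biomarker id with columns gene,
    kind in {site, isoform, motif} and sites (comma-joined constituent
    site ids).  ``dropped`` lists biomarkers removed as background.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("values columns and meta index must match")

    @property
    def biomarkers(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, names: list[str]) -> "BiomarkerMatrix":
        return BiomarkerMatrix(
            self.values[names].copy(), self.meta.loc[names].copy(), list(self.dropped)
        )


def _counts_from_readsets(readsets, panel: SitePanel) -> pd.DataFrame:
    """Tally per-(sample, gene, site, base) counts from aligned read sets."""
    rows = []
    for rs in readsets:
        for gene, codes in rs.calls.items():
            gsites = panel.gene_sites(gene)
            counts = np.zeros((len(gsites), len(BASES)), dtype=np.int64)
            for j in range(codes.shape[1]):
                counts[j] = np.bincount(codes[:, j], minlength=len(BASES))
            for j, site in enumerate(gsites["site"]):
                for b, c in zip(BASES, counts[j]):
                    if c:
                        rows.append((rs.sample_id, gene, site, b, int(c)))
    return pd.DataFrame(rows, columns=["sample", "gene", "site", "base", "count"])


def call_site_editing(
    source, panel: SitePanel, qc: QCConfig | None = None
) -> SiteEditingTable:
    """Compute per-site editing fractions from reads or a count table.

    ``source`` is either an iterable of aligned read sets or a long
    count table with columns (sample, gene, site, base, count).  A
    sample whose total aligned reads fall below ``qc.min_sample_depth``
    is flagged failed-QC and all its fractions are set missing.
    """
    qc = qc or QCConfig()
    extra_samples: list[str] = []
    if isinstance(source, pd.DataFrame):
        counts = source.copy()
        required = {"sample", "gene", "site", "base", "count"}
        if not required.issubset(counts.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
    else:
        source = list(source)
        counts = _counts_from_readsets(source, panel)
        extra_samples = [rs.sample_id for rs in source]  # keeps empty read sets

    strand = panel.sites.set_index("site")["strand"]
    unknown = set(counts["site"]) - set(strand.index)
    if unknown:
        raise ValueError(f"sites not in panel: {sorted(unknown)[:5]}")

    samples = sorted(set(counts["sample"]) | set(extra_samples)) if (
        len(counts) or extra_samples
    ) else []
    rows = []
    sample_depth = {}
    failed = []
    for sample in samples:
        sub = counts[counts["sample"] == sample]
        # each read contributes one base call per site of its gene, so a
        # gene's read count is the maximum per-site total
        per_gene_reads = sub.groupby(["gene", "site"])["count"].sum().groupby("gene").max()
        depth_total = int(per_gene_reads.sum())
        sample_depth[sample] = depth_total
        sample_failed = depth_total < qc.min_sample_depth
        if sample_failed:
            failed.append(sample)
        base_counts = (
            sub.groupby(["gene", "site", "base"])["count"].sum().unstack(fill_value=0)
        )
        for (gene, site), brow in base_counts.iterrows():
            st = strand[site]
            ref = int(brow.get({"+": "A", "-": "T"}[st], 0))
            alt = int(brow.get(ALT_BASE[st], 0))
            depth = ref + alt
            ok = depth >= qc.min_site_depth and not sample_failed
            frac = alt / depth if (ok and depth > 0) else np.nan
            rows.append((sample, gene, site, alt, ref, depth, frac))

    table = pd.DataFrame(
        rows,
        columns=["sample", "gene", "site", "edited", "reference", "depth", "fraction"],
    )
    if failed:
        logger.warning("%d sample(s) failed depth QC: %s", len(failed), failed[:5])
    return SiteEditingTable(
        table, pd.Series(sample_depth, name="sample_depth", dtype="int64"), failed
    )


def call_isoforms(
    readsets, gene: str, panel: SitePanel
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample frequencies of joint per-read editing patterns for a gene.

    A pattern is a binary string over the gene's panel sites in
    positional order ('1' = edited call).  Reads with a call that is
    neither the reference nor the edited base at any site are excluded;
    exclusion counts are returned alongside.

    Returns (frequencies DataFrame samples x patterns, excluded-read
    counts per sample).
    """
    gsites = panel.gene_sites(gene)
    ref_codes = gsites["ref_base"].map(BASE_CODE).to_numpy()
    alt_codes = gsites["strand"].map(ALT_BASE).map(BASE_CODE).to_numpy()
    n_sites = len(gsites)

    freq_rows = {}
    excluded = {}
    for rs in readsets:
        if gene not in rs.calls:
            raise ValueError(f"read set {rs.sample_id!r} has no reads for {gene!r}")
        codes = rs.calls[gene]
        if codes.shape[1] != n_sites:
            raise ValueError(f"read calls for {gene!r} do not cover all panel sites")
        is_ref = codes == ref_codes
        is_alt = codes == alt_codes
        valid = (is_ref | is_alt).all(axis=1)
        excluded[rs.sample_id] = int((~valid).sum())
        edited = is_alt[valid]
        if edited.shape[0] == 0:
            freq_rows[rs.sample_id] = {}
            continue
        pattern_ids = edited @ (1 << np.arange(n_sites))
        ids, cnt = np.unique(pattern_ids, return_counts=True)
        total = cnt.sum()
        freq_rows[rs.sample_id] = {
            format(int(i), f"0{n_sites}b")[::-1]: c / total for i, c in zip(ids, cnt)
        }
    freqs = pd.DataFrame.from_dict(freq_rows, orient="index").fillna(0.0).sort_index(axis=1)
    freqs.index.name = "sample"
    freqs.columns.name = "pattern"
    excl = pd.Series(excluded, name="excluded_reads", dtype="int64")
    if excl.sum():
        logger.info("isoform calling excluded %d reads for %s", int(excl.sum()), gene)
    return freqs, excl


def pattern_counts_table(readsets, panel: SitePanel) -> pd.DataFrame:
    """Per-read joint editing-pattern counts for every gene and sample.

    Long table (sample, gene, pattern, count); reads with an off-base
    call at any site are excluded, mirroring :func:`call_isoforms`.
    """
    rows = []
    for rs in readsets:
        for gene in rs.calls:
            gsites = panel.gene_sites(gene)
            ref_codes = gsites["ref_base"].map(BASE_CODE).to_numpy()
            alt_codes = gsites["strand"].map(ALT_BASE).map(BASE_CODE).to_numpy()
            codes = rs.calls[gene]
            is_ref = codes == ref_codes
            is_alt = codes == alt_codes
            valid = (is_ref | is_alt).all(axis=1)
            edited = is_alt[valid]
            if edited.shape[0] == 0:
                continue
            n_sites = codes.shape[1]
            pattern_ids = edited @ (1 << np.arange(n_sites))
            ids, cnt = np.unique(pattern_ids, return_counts=True)
            for i, c in zip(ids, cnt):
                rows.append(
                    (rs.sample_id, gene, format(int(i), f"0{n_sites}b")[::-1], int(c))
                )
    return pd.DataFrame(rows, columns=["sample", "gene", "pattern", "count"])


def isoforms_from_pattern_counts(
    pattern_counts: pd.DataFrame, gene: str, n_sites: int | None = None
) -> pd.DataFrame:
    """Pattern frequencies from a (sample, gene, pattern, count) table.

    ``n_sites`` restores leading zeros lost when pattern strings were
    round-tripped through a numeric TSV column.
    """
    sub = pattern_counts[pattern_counts["gene"] == gene].copy()
    if sub.empty:
        raise ValueError(f"no pattern counts for gene {gene!r}")
    sub["pattern"] = sub["pattern"].astype(str)
    if n_sites is not None:
        sub["pattern"] = sub["pattern"].str.zfill(n_sites)
    wide = sub.pivot_table(
        index="sample", columns="pattern", values="count", aggfunc="sum", fill_value=0
    )
    freqs = wide.div(wide.sum(axis=1), axis=0)
    freqs.index.name = "sample"
    return freqs.sort_index(axis=1)


def pattern_marginals(freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-site marginal editing implied by pattern frequencies.

    Column j of the result is the summed frequency of patterns edited at
    site j (an exact identity used as an internal consistency check).
    """
    patterns = [np.array([ch == "1" for ch in p]) for p in freqs.columns]
    n_sites = len(patterns[0]) if patterns else 0
    out = np.zeros((len(freqs), n_sites))
    for p, col in zip(patterns, freqs.columns):
        out += np.outer(freqs[col].to_numpy(), p)
    return pd.DataFrame(out, index=freqs.index, columns=[f"site_{j}" for j in range(n_sites)])


def build_biomarker_matrix(
    sites: SiteEditingTable,
    isoforms: dict[str, pd.DataFrame] | None = None,
    qc: QCConfig | None = None,
    motif_groups: dict[str, tuple[str, list[str]]] | None = None,
) -> BiomarkerMatrix:
    """Assemble the biomarker matrix and drop background biomarkers.

    Site biomarkers are editing fractions; isoform biomarkers are the
    per-gene pattern frequencies from :func:`call_isoforms`; a motif
    biomarker is the mean fraction over a declared group of sites
    (``motif_groups``: name -> (gene, [site ids])).  Biomarkers whose
    cohort median is below ``qc.background_threshold`` are dropped.
    """
    qc = qc or QCConfig()
    frac = sites.fractions()
    if sites.failed_samples:
        frac = frac.drop(index=[s for s in sites.failed_samples if s in frac.index])
    if frac.dropna(how="all").empty:
        raise ValueError("no QC-passing samples with editing values")

    site_gene = sites.table.drop_duplicates("site").set_index("site")["gene"]
    values = {c: frac[c] for c in frac.columns}
    meta_rows = {
        c: {"gene": site_gene[c], "kind": "site", "sites": c} for c in frac.columns
    }

    if isoforms:
        for gene, fdf in isoforms.items():
            fdf = fdf.reindex(frac.index)
            for pattern in fdf.columns:
                name = f"{gene}:iso:{pattern}"
                values[name] = fdf[pattern]
                meta_rows[name] = {"gene": gene, "kind": "isoform", "sites": ""}

    if motif_groups:
        for name, (gene, group_sites) in motif_groups.items():
            missing = [s for s in group_sites if s not in frac.columns]
            if missing:
                raise ValueError(f"motif {name!r} references unknown sites {missing}")
            key = f"{gene}:motif:{name}"
            values[key] = frac[group_sites].mean(axis=1)
            meta_rows[key] = {
                "gene": gene,
                "kind": "motif",
                "sites": ",".join(group_sites),
            }

    mat = pd.DataFrame(values)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "biomarker"

    medians = mat.median(axis=0, skipna=True)
    # strict '<': a zero threshold drops nothing
    dropped = list(medians.index[medians < qc.background_threshold])
    kept = [c for c in mat.columns if c not in dropped]
    if not kept:
        raise ValueError("background filtering dropped every biomarker")
    if dropped:
        logger.info("background filter dropped %d biomarkers", len(dropped))
    return BiomarkerMatrix(mat[kept], meta.loc[kept], dropped)


def gene_global_editing(sites: SiteEditingTable) -> pd.DataFrame:
    """Per-(sample, gene) global editing: pooled edited / (edited+reference)."""
    t = sites.table
    grp = t.groupby(["sample", "gene"])[["edited", "reference"]].sum()
    denom = grp["edited"] + grp["reference"]
    with np.errstate(invalid="ignore"):
        ge = grp["edited"] / denom.replace(0, np.nan)
    return ge.unstack("gene")


def normalize_by_global_editing(
    matrix: BiomarkerMatrix, sites: SiteEditingTable
) -> BiomarkerMatrix:
    """Divide each biomarker by its gene's per-sample global editing.

    Samples with zero global editing for a gene get missing values for
    that gene's biomarkers (flagged in the log).
    """
    ge = gene_global_editing(sites)
    missing_genes = set(matrix.meta["gene"]) - set(ge.columns)
    if missing_genes:
        raise ValueError(f"genes absent from site table: {sorted(missing_genes)}")
    ge = ge.reindex(matrix.values.index)
    ge = ge.mask(ge == 0)  # zero global editing -> missing, not division by zero
    zero_cells = int(ge.isna().sum().sum())
    if zero_cells:
        warnings.warn(
            f"{zero_cells} (sample, gene) cells have zero/undefined global editing; "
            "their normalized values are missing",
            stacklevel=2,
        )
    out = matrix.values.copy()
    for bm in out.columns:
        out[bm] = out[bm] / ge[matrix.meta.loc[bm, "gene"]]
    return BiomarkerMatrix(out, matrix.meta.copy(), list(matrix.dropped))
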