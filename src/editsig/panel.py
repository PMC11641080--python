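"""Editing-site panel: the genomic positions interrogated per gene.

A :class:`SitePanel` lists the candidate A-to-I editing positions of the
targeted amplicon panel.  On the + strand an edited adenosine reads as G,
on the − strand (reverse-complement sequencing) the reference base is T
and the edited call is C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .constants import GENES

#: reference base expected on each strand, and the base an edited
#: position reads as.
REF_BASE = {"+": "A", "-": "T"}
ALT_BASE = {"+": "G", "-": "C"}


@dataclass(frozen=True)
class SitePanel:
    """Immutable table of candidate editing sites.

    ``sites`` columns: gene, site (unique id), position (0-based),
    strand (+/−), ref_base.
    """

    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"gene", "site", "position", "strand", "ref_base"}
        missing = required - set(self.sites.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.sites["site"].duplicated().any():
            raise ValueError("duplicate site ids in panel")
        dup = self.sites.duplicated(subset=["gene", "position"])
        if dup.any():
            raise ValueError("duplicate positions within a gene")
        bad_strand = ~self.sites["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError("strand must be '+' or '-'")
        expected = self.sites["strand"].map(REF_BASE)
        if (self.sites["ref_base"] != expected).any():
            raise ValueError("reference base must be A on + strand, T on - strand")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.sites["gene"]))

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site"])

    def gene_sites(self, gene: str) -> pd.DataFrame:
        """Rows for one gene, in panel (positional) order."""
        sub = self.sites[self.sites["gene"] == gene]
        if sub.empty:
            raise KeyError(f"gene {gene!r} not in panel")
        return sub.sort_values("position").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)


# Per-gene site counts of the default panel.  The amplicon coordinates are
# synthetic placeholders (no public per-site coordinates exist for the
# panel); what matters downstream is the gene/site/strand structure.
_DEFAULT_SITE_COUNTS = {
    "CAMK1D": 5,
    "GAB2": 8,
    "IFNAR1": 7,
    "KCNJ15": 5,
    "LYN": 5,
    "MDM2": 7,
    "PDE8A": 3,
    "PRKCB": 5,
}
_MINUS_STRAND_GENES = {"GAB2", "PDE8A"}


def default_panel() -> SitePanel:
    """The default 8-gene editing-site panel (45 sites).

    Site positions are evenly spaced synthetic amplicon coordinates;
    two genes are placed on the − strand to exercise both strand
    conventions.
    """
    rows = []
    for gene in GENES:
        strand = "-" if gene in _MINUS_STRAND_GENES else "+"
        for k in range(_DEFAULT_SITE_COUNTS[gene]):
            pos = 100 + 37 * k
            rows.append(
                {
                    "gene": gene,
                    "site": f"{gene}_{pos}",
                    "position": pos,
                    "strand": strand,
                    "ref_base": REF_BASE[strand],
                }
            )
    return SitePanel(pd.DataFrame(rows))


def write_bed(panel: SitePanel, path: str | Path) -> None:
    """Write the panel as 6-column BED (0-based half-open, strand in col 6)."""
    df = panel.sites
    bed = pd.DataFrame(
        {
            "chrom": df["gene"],
            "start": df["position"],
            "end": df["position"] + 1,
            "name": df["site"],
            "score": 0,
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> SitePanel:
    """Read a 6-column BED site panel written by :func:`write_bed`."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if ((bed["end"] - bed["start"]) != 1).any():
        raise ValueError("panel BED intervals must be single-base")
    sites = pd.DataFrame(
        {
            "gene": bed["chrom"],
            "site": bed["name"],
            "position": bed["start"],
            "strand": bed["strand"],
            "ref_base": bed["strand"].map(REF_BASE),
        }
    )
    return SitePanel(sites)
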