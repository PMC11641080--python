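"""Editing quantification: strand conventions, QC, isoforms, normalization."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from editsig import (
    QCConfig,
    build_biomarker_matrix,
    call_isoforms,
    call_site_editing,
    generate_reads,
    normalize_by_global_editing,
)
from editsig.quant import (
    _counts_from_readsets,
    gene_global_editing,
    isoforms_from_pattern_counts,
    pattern_counts_table,
    pattern_marginals,
)
from editsig.synthetic import AlignedReadSet


def _counts(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "site", "base", "count"])


def _qc_small():
    return QCConfig(min_sample_depth=10, min_site_depth=10)


class TestCallSiteEditing:
    def test_plus_strand_fraction(self, panel):
        counts = _counts(
            [("s1", "CAMK1D", "CAMK1D_100", "A", 90), ("s1", "CAMK1D", "CAMK1D_100", "G", 10)]
        )
        out = call_site_editing(counts, panel, _qc_small())
        assert out.table["fraction"].iloc[0] == pytest.approx(0.10)

    def test_minus_strand_fraction(self, panel):
        counts = _counts(
            [("s1", "PDE8A", "PDE8A_100", "T", 70), ("s1", "PDE8A", "PDE8A_100", "C", 30)]
        )
        out = call_site_editing(counts, panel, _qc_small())
        assert out.table["fraction"].iloc[0] == pytest.approx(0.30)

    def test_other_bases_excluded_from_denominator(self, panel):
        counts = _counts(
            [
                ("s1", "CAMK1D", "CAMK1D_100", "A", 60),
                ("s1", "CAMK1D", "CAMK1D_100", "G", 20),
                ("s1", "CAMK1D", "CAMK1D_100", "C", 20),
            ]
        )
        out = call_site_editing(counts, panel, _qc_small())
        assert out.table["fraction"].iloc[0] == pytest.approx(0.25)

    def test_sample_below_depth_floor_flagged(self, panel):
        counts = _counts([("lo", "CAMK1D", "CAMK1D_100", "A", 9_999)])
        out = call_site_editing(counts, panel, QCConfig())
        assert out.failed_samples == ["lo"]
        assert out.table["fraction"].isna().all()

    def test_empty_read_set_is_failed_qc(self, panel):
        rs = AlignedReadSet("empty", {})
        out = call_site_editing([rs], panel, QCConfig())
        assert out.failed_samples == ["empty"]

    def test_round_trip_recovers_proportions(self, small_spec):
        spec = replace(small_spec, reads_per_sample=10_000, seq_error=0.0)
        prop = pd.Series(0.12, index=spec.site_panel.site_ids)
        rs = generate_reads(spec, prop, sample_id="rt", seed=31)
        out = call_site_editing([rs], spec.site_panel, QCConfig())
        sigma = np.sqrt(0.12 * 0.88 / 10_000)
        assert (out.table["fraction"] - 0.12).abs().max() < 3 * sigma


class TestIsoforms:
    def test_counting_example(self, panel):
        # 10 reads over 2 sites: 4 unedited, 3 edited s1, 2 edited s2, 1 both
        gene = "KCNJ15"
        n_sites = len(panel.gene_sites(gene))
        codes = np.zeros((10, n_sites), dtype=np.uint8)  # all 'A' (ref)
        codes[4:7, 0] = 2
        codes[7:9, 1] = 2
        codes[9, :2] = 2
        rs = AlignedReadSet("iso", {gene: codes})
        freqs, excl = call_isoforms([rs], gene, panel)
        zero = "0" * n_sites
        assert freqs.loc["iso", zero] == pytest.approx(0.4)
        assert freqs.loc["iso", "10" + zero[2:]] == pytest.approx(0.3)
        assert freqs.loc["iso", "01" + zero[2:]] == pytest.approx(0.2)
        assert freqs.loc["iso", "11" + zero[2:]] == pytest.approx(0.1)
        marg = pattern_marginals(freqs)
        assert marg.loc["iso", "site_0"] == pytest.approx(0.4)
        assert marg.loc["iso", "site_1"] == pytest.approx(0.3)
        assert excl["iso"] == 0

    def test_all_unedited_single_pattern(self, panel):
        gene = "LYN"
        n_sites = len(panel.gene_sites(gene))
        rs = AlignedReadSet("u", {gene: np.zeros((5, n_sites), dtype=np.uint8)})
        freqs, _ = call_isoforms([rs], gene, panel)
        assert list(freqs.columns) == ["0" * n_sites]
        assert freqs.iloc[0, 0] == 1.0

    def test_marginal_consistency_on_random_phased_reads(self, small_spec):
        rng = np.random.default_rng(41)
        prop = pd.Series(
            rng.uniform(0.05, 0.5, len(small_spec.site_panel.site_ids)),
            index=small_spec.site_panel.site_ids,
        )
        spec = replace(small_spec, seq_error=0.0)
        rs = generate_reads(spec, prop, sample_id="m", seed=42)
        for gene in ("GAB2", "MDM2"):
            freqs, _ = call_isoforms([rs], gene, small_spec.site_panel)
            marg = pattern_marginals(freqs).iloc[0].to_numpy()
            codes = rs.calls[gene]
            gsites = small_spec.site_panel.gene_sites(gene)
            alt = {"+": 2, "-": 1}[gsites["strand"].iloc[0]]
            direct = (codes == alt).mean(axis=0)
            np.testing.assert_allclose(marg, direct, atol=1e-12)

    def test_pattern_count_round_trip(self, small_spec):
        prop = pd.Series(0.2, index=small_spec.site_panel.site_ids)
        rs = generate_reads(small_spec, prop, sample_id="pc", seed=43)
        table = pattern_counts_table([rs], small_spec.site_panel)
        gene = "IFNAR1"
        n_sites = len(small_spec.site_panel.gene_sites(gene))
        via_table = isoforms_from_pattern_counts(table, gene, n_sites)
        direct, _ = call_isoforms([rs], gene, small_spec.site_panel)
        pd.testing.assert_frame_equal(via_table, direct, check_like=True)


class TestBackgroundFilter:
    def _sites(self, panel, values):
        rows = []
        for sample, per_site in values.items():
            for site, frac in per_site.items():
                gene = site.rsplit("_", 1)[0]
                rows.append((sample, gene, site, int(frac * 1000), 1000 - int(frac * 1000), 1000, frac))
        from editsig.quant import SiteEditingTable

        table = pd.DataFrame(
            rows,
            columns=["sample", "gene", "site", "edited", "reference", "depth", "fraction"],
        )
        depth = table.groupby("sample")["depth"].sum()
        return SiteEditingTable(table, depth, [])

    def test_zero_median_site_dropped(self, panel):
        sites = self._sites(
            panel,
            {
                s: {"CAMK1D_100": 0.0, "CAMK1D_137": 0.1}
                for s in ("a", "b", "c")
            },
        )
        out = build_biomarker_matrix(sites, qc=QCConfig(background_threshold=0.005))
        assert out.dropped == ["CAMK1D_100"]

    def test_zero_threshold_drops_nothing(self, panel):
        # median < threshold is strict, so threshold 0 keeps even all-zero sites
        sites = self._sites(
            panel, {s: {"CAMK1D_100": 0.0, "CAMK1D_137": 0.1} for s in ("a", "b", "c")}
        )
        out = build_biomarker_matrix(sites, qc=QCConfig(background_threshold=0.0))
        assert out.dropped == []
        assert sorted(out.values.columns) == ["CAMK1D_100", "CAMK1D_137"]

    def test_planted_background_separation(self, panel):
        rng = np.random.default_rng(7)
        signal_sites = ["GAB2_100", "GAB2_137"]
        noise_sites = ["GAB2_174", "GAB2_211"]
        values = {
            f"s{i}": {
                **{s: float(rng.normal(0.1, 0.01)) for s in signal_sites},
                **{s: float(abs(rng.normal(0.001, 0.0005))) for s in noise_sites},
            }
            for i in range(20)
        }
        sites = self._sites(panel, values)
        out = build_biomarker_matrix(sites, qc=QCConfig(background_threshold=0.005))
        assert sorted(out.dropped) == sorted(noise_sites)
        assert sorted(out.values.columns) == sorted(signal_sites)


class TestNormalization:
    def _sites_with_counts(self, rows):
        from editsig.quant import SiteEditingTable

        table = pd.DataFrame(
            rows,
            columns=["sample", "gene", "site", "edited", "reference", "depth", "fraction"],
        )
        return SiteEditingTable(table, table.groupby("sample")["depth"].sum(), [])

    def test_ratio_example(self):
        # biomarker 0.30 against gene global editing 0.15 -> 2.0
        sites = self._sites_with_counts(
            [
                ("s1", "LYN", "LYN_100", 30, 70, 100, 0.30),
                ("s1", "LYN", "LYN_137", 0, 100, 100, 0.0),
            ]
        )
        from editsig.quant import BiomarkerMatrix

        matrix = BiomarkerMatrix(
            pd.DataFrame({"LYN_100": [0.30]}, index=["s1"]),
            pd.DataFrame(
                {"gene": ["LYN"], "kind": ["site"], "sites": ["LYN_100"]},
                index=["LYN_100"],
            ),
        )
        out = normalize_by_global_editing(matrix, sites)
        assert out.values.loc["s1", "LYN_100"] == pytest.approx(0.30 / 0.15)

    def test_single_site_gene_normalizes_to_one(self):
        sites = self._sites_with_counts([("s1", "PDE8A", "PDE8A_100", 25, 75, 100, 0.25)])
        from editsig.quant import BiomarkerMatrix

        matrix = BiomarkerMatrix(
            pd.DataFrame({"PDE8A_100": [0.25]}, index=["s1"]),
            pd.DataFrame(
                {"gene": ["PDE8A"], "kind": ["site"], "sites": ["PDE8A_100"]},
                index=["PDE8A_100"],
            ),
        )
        out = normalize_by_global_editing(matrix, sites)
        assert out.values.loc["s1", "PDE8A_100"] == pytest.approx(1.0)

    def test_zero_global_editing_flagged_missing(self):
        sites = self._sites_with_counts([("s1", "MDM2", "MDM2_100", 0, 100, 100, 0.0)])
        from editsig.quant import BiomarkerMatrix

        matrix = BiomarkerMatrix(
            pd.DataFrame({"MDM2_100": [0.0]}, index=["s1"]),
            pd.DataFrame(
                {"gene": ["MDM2"], "kind": ["site"], "sites": ["MDM2_100"]},
                index=["MDM2_100"],
            ),
        )
        with pytest.warns(UserWarning, match="global editing"):
            out = normalize_by_global_editing(matrix, sites)
        assert np.isnan(out.values.loc["s1", "MDM2_100"])

    def test_scale_free_in_counts(self):
        rows = [
            ("s1", "LYN", "LYN_100", 30, 70, 100, 0.30),
            ("s1", "LYN", "LYN_137", 10, 90, 100, 0.10),
        ]
        scaled = [(s, g, site, e * 7, r * 7, d * 7, f) for s, g, site, e, r, d, f in rows]
        from editsig.quant import BiomarkerMatrix

        matrix = BiomarkerMatrix(
            pd.DataFrame({"LYN_100": [0.30], "LYN_137": [0.10]}, index=["s1"]),
            pd.DataFrame(
                {"gene": ["LYN", "LYN"], "kind": ["site"] * 2, "sites": ["LYN_100", "LYN_137"]},
                index=["LYN_100", "LYN_137"],
            ),
        )
        a = normalize_by_global_editing(matrix, self._sites_with_counts(rows))
        b = normalize_by_global_editing(matrix, self._sites_with_counts(scaled))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_missing_gene_errors(self):
        sites = self._sites_with_counts([("s1", "LYN", "LYN_100", 30, 70, 100, 0.3)])
        from editsig.quant import BiomarkerMatrix

        matrix = BiomarkerMatrix(
            pd.DataFrame({"GAB2_100": [0.2]}, index=["s1"]),
            pd.DataFrame(
                {"gene": ["GAB2"], "kind": ["site"], "sites": ["GAB2_100"]},
                index=["GAB2_100"],
            ),
        )
        with pytest.raises(ValueError, match="absent"):
            normalize_by_global_editing(matrix, sites)
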