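"""Linker and hypergeometric enrichment tests, including exhaustive oracles."""

import itertools
import math

import numpy as np
import pytest

from rretools.core import GeneModel, Interval, Peak, overlaps
from rretools.peak_gene import (
    EnrichmentResult,
    cne_overlap_enrichment,
    de_gene_rre_enrichment,
    gene_windows,
    hypergeom_upper_tail,
    hypergeom_upper_tail_cdf_form,
    link_peaks_to_genes,
)

from conftest import random_peaks


def enumeration_upper_tail(n, n1, n2, m):
    """Exhaustive oracle: enumerate all C(n, n2) draws, count overlaps >= m."""
    marked = set(range(n1))
    total = extreme = 0
    for draw in itertools.combinations(range(n), n2):
        total += 1
        if len(marked.intersection(draw)) >= m:
            extreme += 1
    return extreme / total


class TestGeneWindows:
    SIZES = {"chr1": 1_000_000}

    def test_symmetric_extension_ignores_strand(self):
        plus = GeneModel("g", "chr1", 100_000, 101_000, "+")
        minus = GeneModel("g", "chr1", 100_000, 101_000, "-")
        w_plus = gene_windows([plus], self.SIZES)["g"]
        w_minus = gene_windows([minus], self.SIZES)["g"]
        assert (w_plus.start, w_plus.end) == (w_minus.start, w_minus.end)

    def test_window_arithmetic(self):
        g = GeneModel("g", "chr1", 100_000, 101_000, "+")
        w = gene_windows([g], self.SIZES)["g"]
        assert (w.start, w.end) == (50_000, 151_000)

    def test_clipped_at_zero(self):
        g = GeneModel("g", "chr1", 10_000, 11_000, "+")
        w = gene_windows([g], self.SIZES)["g"]
        assert w.start == 0

    def test_clipped_at_chromosome_end(self):
        g = GeneModel("g", "chr1", 990_000, 995_000, "+")
        w = gene_windows([g], self.SIZES)["g"]
        assert w.end == 1_000_000

    def test_asymmetric_swapped_for_minus_strand(self):
        g = GeneModel("g", "chr1", 500_000, 501_000, "-")
        w = gene_windows([g], self.SIZES, left=10_000, right=1_000)["g"]
        # -sw: left/right refer to the gene's own orientation
        assert (w.start, w.end) == (499_000, 511_000)

    def test_missing_chromosome_size(self):
        g = GeneModel("g", "chrX", 1000, 2000, "+")
        with pytest.raises(ValueError, match="chrX"):
            gene_windows([g], self.SIZES)


class TestLinkPeaksToGenes:
    SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}

    def _links(self, peaks, genes):
        windows = gene_windows(genes, self.SIZES)
        return link_peaks_to_genes(peaks, genes, windows)

    def test_far_peak_unlinked(self, toy_genes):
        peak = Peak("chr1", 600_000, 600_200, "p")
        assert self._links([peak], toy_genes) == []

    def test_containment_link(self):
        gene = GeneModel("g", "chr1", 100_000, 101_000, "+")
        peak = Peak("chr1", 149_500, 149_600, "p")
        links = self._links([peak], [gene])
        assert len(links) == 1 and links[0].gene_id == "g"

    def test_distance_zero_on_gene_body_overlap(self):
        gene = GeneModel("g", "chr1", 100_000, 101_000, "+")
        peak = Peak("chr1", 100_500, 100_700, "p")
        assert self._links([peak], [gene])[0].distance == 0

    def test_distance_sign_convention(self):
        gene = GeneModel("g", "chr1", 100_000, 101_000, "+")
        upstream = Peak("chr1", 98_000, 98_200, "u")  # TSS side for '+'
        downstream = Peak("chr1", 103_000, 103_200, "d")
        links = {l.peak_id: l for l in self._links([upstream, downstream], [gene])}
        assert links["u"].distance == -1800
        assert links["d"].distance == 2000
        # for a '-' gene the signs flip
        gene_m = GeneModel("g", "chr1", 100_000, 101_000, "-")
        links_m = {l.peak_id: l for l in self._links([upstream, downstream], [gene_m])}
        assert links_m["u"].distance == 1800
        assert links_m["d"].distance == -2000

    def test_bookended_window_not_linked(self):
        gene = GeneModel("g", "chr1", 100_000, 101_000, "+")
        peak = Peak("chr1", 151_000, 151_200, "p")  # starts exactly at window end
        assert self._links([peak], [gene]) == []

    @pytest.mark.parametrize("trial", range(25))
    def test_oracle_equivalence(self, trial):
        rng = np.random.default_rng(3000 + trial)
        genes = []
        for i in range(10):
            chrom = ("chr1", "chr2")[rng.integers(2)]
            start = int(rng.integers(0, 800_000))
            genes.append(
                GeneModel(f"g{i}", chrom, start, start + int(rng.integers(500, 5000)),
                          ("+", "-")[rng.integers(2)])
            )
        peaks = random_peaks(rng, 50, span=900_000)
        got = {(l.peak_id, l.gene_id) for l in self._links(peaks, genes)}
        expected = set()
        for p in peaks:
            for g in genes:
                if p.chrom == g.chrom and overlaps(
                    p.start, p.end, max(0, g.start - 50_000), g.end + 50_000
                ):
                    expected.add((p.peak_id, g.gene_id))
        assert got == expected


class TestHypergeomUpperTail:
    def test_m_zero_full_tail(self):
        assert hypergeom_upper_tail(100, 10, 10, 0) == 0.0

    def test_worked_value_55_over_210(self):
        log10_p = hypergeom_upper_tail(10, 5, 4, 3)
        assert 10**log10_p == pytest.approx(55 / 210, rel=1e-12)
        assert enumeration_upper_tail(10, 5, 4, 3) == pytest.approx(55 / 210)

    def test_worked_value_one_sixth(self):
        log10_p = hypergeom_upper_tail(4, 2, 2, 2)
        assert 10**log10_p == pytest.approx(1 / 6, rel=1e-12)
        assert enumeration_upper_tail(4, 2, 2, 2) == pytest.approx(1 / 6)

    def test_m_above_min_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 4, 5)

    def test_saturation_p_one(self):
        assert hypergeom_upper_tail(50, 20, 50, 20) == 0.0

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_exhaustive_enumeration_small_n(self, n):
        for n1 in range(n + 1):
            for n2 in range(1, n + 1):
                for m in range(min(n1, n2) + 1):
                    expected = enumeration_upper_tail(n, n1, n2, m)
                    got = 10 ** hypergeom_upper_tail(n, n1, n2, m)
                    assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_monotone_in_m(self):
        vals = [hypergeom_upper_tail(200, 40, 60, m) for m in range(0, 41)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_matches_cdf_difference_form_at_moderate_p(self):
        for n, n1, n2, m in [(100, 30, 40, 15), (500, 100, 80, 20), (50, 25, 20, 14)]:
            log_tail = hypergeom_upper_tail(n, n1, n2, m)
            cdf_form = hypergeom_upper_tail_cdf_form(n, n1, n2, m)
            assert 10**log_tail == pytest.approx(cdf_form, rel=1e-8)

    def test_extreme_tail_stays_finite(self):
        log10_p = hypergeom_upper_tail(25_592, 13_000, 3_000, 3_000)
        assert math.isfinite(log10_p)
        assert log10_p <= -300


class TestEnrichmentWrappers:
    def test_disjoint_de_set(self):
        from rretools.peak_gene import PeakGeneLink

        links = [PeakGeneLink("p1", "g1", 0)]
        res = de_gene_rre_enrichment(["g2"], links, ["g1", "g2", "g3"])
        assert res.m == 0 and res.log10_p == 0.0

    def test_saturated_de_set(self):
        from rretools.peak_gene import PeakGeneLink

        universe = [f"g{i}" for i in range(10)]
        links = [PeakGeneLink("p1", "g1", 0), PeakGeneLink("p2", "g5", 0)]
        res = de_gene_rre_enrichment(universe, links, universe)
        assert res.m == res.n1 and res.log10_p == 0.0

    def test_missing_de_gene_excluded_with_warning(self, caplog):
        from rretools.peak_gene import PeakGeneLink

        links = [PeakGeneLink("p1", "g1", 0)]
        with caplog.at_level("WARNING"):
            res = de_gene_rre_enrichment(["g1", "ghost"], links, ["g1", "g2"])
        assert res.n2 == 1
        assert "excluded" in caplog.text

    def test_invariants(self):
        res = EnrichmentResult(n=100, n1=20, n2=30, m=10, log10_p=-3.0)
        assert res.expected_overlap == pytest.approx(6.0)
        assert 0 <= res.m <= min(res.n1, res.n2)

    def test_no_cnes(self):
        peaks = [Peak("chr1", 0, 100, "p1"), Peak("chr1", 1000, 1100, "p2")]
        count, res = cne_overlap_enrichment(["p1"], [], peaks)
        assert count == 0 and res.log10_p == 0.0

    def test_bookended_cne_not_overlap(self):
        peaks = [Peak("chr1", 100, 200, "p1")]
        cnes = [Interval("chr1", 200, 300)]
        count, _ = cne_overlap_enrichment([], cnes, peaks)
        assert count == 0


def test_null_p_values_approximately_uniform():
    """DE sets drawn uniformly give approximately uniform upper-tail p-values."""
    from scipy.stats import kstest

    rng = np.random.default_rng(5)
    n, n1, n2 = 5000, 1000, 500
    universe = np.arange(n)
    linked = set(range(n1))
    ps = []
    for _ in range(500):
        de = rng.choice(universe, size=n2, replace=False)
        m = len(linked.intersection(de))
        ps.append(10 ** hypergeom_upper_tail(n, n1, n2, m))
    stat = kstest(ps, "uniform").statistic
    assert stat < 0.1


def test_default_synthetic_enrichment(default_config, default_genome, default_sim):
    """Planted structure yields DE-RRE and CNE-RRE enrichment below 1e-2."""
    from rretools.synthetic import make_cnes, make_de_genes

    sizes, genes = default_genome
    truth = default_sim.truth
    de = make_de_genes(default_genome, truth, default_config)
    windows = gene_windows(genes, sizes)
    all_emerging = [p for ps in truth.emerging_peaks.values() for p in ps]
    links = link_peaks_to_genes(all_emerging, genes, windows)
    enr = de_gene_rre_enrichment(de["gene_id"], links, [g.gene_id for g in genes])
    assert enr.log10_p < -2

    de_set = set(de["gene_id"])
    de_linked = {l.peak_id for l in links if l.gene_id in de_set}
    cnes = make_cnes(truth, default_config, prefer_ids=de_linked)
    _, cne_enr = cne_overlap_enrichment(de_linked, cnes, all_emerging)
    assert cne_enr.log10_p < -2
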