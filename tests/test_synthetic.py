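"""Determinism, conservation and limit-case tests for the simulator."""

import json

import numpy as np
import pytest
from scipy import stats as scipy_stats

from rretools.core import overlaps
from rretools.motiflib import builtin_motifs, information_content
from rretools.synthetic import (
    PlantPlan,
    SyntheticConfig,
    TruthManifest,
    make_cnes,
    make_de_genes,
    make_genome,
    make_sequences,
    simulate_all,
    simulate_peaks_and_counts,
)


class TestConfig:
    def test_bad_probability(self):
        with pytest.raises(ValueError, match="gc_content"):
            SyntheticConfig(gc_content=1.5)

    def test_short_chromosome(self):
        with pytest.raises(ValueError):
            SyntheticConfig(chromosome_length=5000)

    def test_fold_change_below_one(self):
        with pytest.raises(ValueError):
            SyntheticConfig(accessibility_fold_change=0.5)

    def test_negative_count(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=-1)


class TestMakeGenome:
    def test_empty_gene_set(self):
        sizes, genes = make_genome(SyntheticConfig(n_chromosomes=2, n_genes=0))
        assert genes == [] and len(sizes) == 2

    def test_determinism(self, tmp_path):
        from rretools.io import write_gtf

        cfg = SyntheticConfig(seed=1)
        for run in ("a", "b"):
            _, genes = make_genome(cfg)
            write_gtf(genes, tmp_path / f"{run}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_genes_within_bounds_and_disjoint(self):
        cfg = SyntheticConfig(n_genes=50, chromosome_length=1_000_000, n_chromosomes=2)
        sizes, genes = make_genome(cfg)
        assert len(genes) == 50
        for g in genes:
            assert 0 <= g.start < g.end <= sizes[g.chrom]
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.start)
            for a, b in zip(glist, glist[1:]):
                assert a.end <= b.start

    def test_infeasible_packing(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_genome(
                SyntheticConfig(n_genes=50, chromosome_length=10_000, n_chromosomes=1)
            )

    def test_tss_convention(self):
        _, genes = make_genome(SyntheticConfig(seed=3))
        for g in genes:
            assert g.tss == (g.start if g.strand == "+" else g.end - 1)


class TestSimulatePeaksAndCounts:
    def test_null_case_identical_sets(self, default_genome):
        cfg = SyntheticConfig(
            accessibility_fold_change=1.0, n_peaks_emerging_per_celltype=0, seed=7
        )
        sim = simulate_peaks_and_counts(cfg, default_genome)
        for ct in cfg.cell_types:
            treated = [(p.chrom, p.center) for p in sim.treated_peaks[ct]]
            control = [(p.chrom, p.center) for p in sim.control_peaks[ct]]
            assert len(treated) == len(control)
            for (tc, tcen), (cc, ccen) in zip(treated, control):
                assert tc == cc and abs(tcen - ccen) <= 20  # jitter only

    def test_treated_record_count(self, default_genome):
        cfg = SyntheticConfig(
            n_peaks_shared=100, n_peaks_emerging_per_celltype=20, seed=7
        )
        sim = simulate_peaks_and_counts(cfg, default_genome)
        assert len(sim.treated_peaks["SC"]) == 120

    def test_counts_deterministic(self, default_config, default_genome):
        a = simulate_peaks_and_counts(default_config, default_genome)
        b = simulate_peaks_and_counts(default_config, default_genome)
        for ct in default_config.cell_types:
            assert np.array_equal(
                a.count_matrices[ct].counts, b.count_matrices[ct].counts
            )

    def test_too_few_cells(self, default_genome):
        with pytest.raises(ValueError):
            simulate_peaks_and_counts(
                SyntheticConfig(n_cells_per_group=1), default_genome
            )

    def test_truth_ids_exist_in_peaks(self, default_config, default_sim):
        for ct in default_config.cell_types:
            emitted = {p.peak_id for p in default_sim.treated_peaks[ct]}
            for pid in default_sim.truth.emerging_peak_ids[ct]:
                assert pid in emitted

    def test_half_of_emerging_near_genes(self, default_config, default_genome, default_sim):
        _, genes = default_genome
        near = 0
        all_emerging = [
            p for ps in default_sim.truth.emerging_peaks.values() for p in ps
        ]
        for p in all_emerging:
            if any(
                g.chrom == p.chrom
                and overlaps(p.start, p.end, g.start - 50_000, g.end + 50_000)
                for g in genes
            ):
                near += 1
        assert near >= len(all_emerging) / 2


class TestMakeDeGenes:
    def test_all_zero_rates_empty(self, default_genome, default_sim):
        cfg = SyntheticConfig(
            de_gene_fraction_near_rre=0.0, de_background_rate=0.0, seed=7
        )
        de = make_de_genes(default_genome, default_sim.truth, cfg)
        assert de.empty

    def test_limit_equals_near_set(self, default_genome, default_sim):
        cfg = SyntheticConfig(
            de_gene_fraction_near_rre=1.0, de_background_rate=0.0, seed=7
        )
        truth = default_sim.truth
        de = make_de_genes(default_genome, truth, cfg)
        assert set(de["gene_id"]) == set(truth.genes_near_rre)


class TestMakeCnes:
    def test_zero_fraction_no_overlap(self, default_sim):
        cfg = SyntheticConfig(cne_overlap_fraction=0.0, seed=7)
        cnes = make_cnes(default_sim.truth, cfg)
        all_emerging = [
            p for ps in default_sim.truth.emerging_peaks.values() for p in ps
        ]
        for c in cnes:
            for p in all_emerging:
                if p.chrom == c.chrom:
                    assert not overlaps(c.start, c.end, p.start, p.end)

    def test_full_fraction_all_overlap(self, default_sim):
        cfg = SyntheticConfig(cne_overlap_fraction=1.0, seed=7)
        cnes = make_cnes(default_sim.truth, cfg)
        all_emerging = [
            p for ps in default_sim.truth.emerging_peaks.values() for p in ps
        ]
        for p in all_emerging:
            assert any(
                c.chrom == p.chrom and overlaps(c.start, c.end, p.start, p.end)
                for c in cnes
            )

    def test_exact_overlap_count(self, default_sim):
        """Interval-intersection oracle: half the emerging peaks get a CNE."""
        cfg = SyntheticConfig(cne_overlap_fraction=0.5, seed=7)
        truth = default_sim.truth
        cnes = make_cnes(truth, cfg)
        all_emerging = [p for ps in truth.emerging_peaks.values() for p in ps]
        overlapping = {
            p.peak_id
            for p in all_emerging
            if any(
                c.chrom == p.chrom and overlaps(c.start, c.end, p.start, p.end)
                for c in cnes
            )
        }
        assert len(overlapping) == round(0.5 * len(all_emerging))
        assert set(truth.cne_overlapping_rre_ids) == overlapping


class TestMakeSequences:
    def _plain_config(self, **kw):
        return SyntheticConfig(n_positives=50, n_controls=60, seed=7, **kw)

    def test_zero_frequency_pure_background(self):
        truth = TruthManifest()
        cfg = self._plain_config(
            motif_plant_frequency=0.0, cooccur_plant_frequency=0.0
        )
        pos, ctrl = make_sequences(truth, cfg)
        assert truth.planted_motif_instances == []
        assert all(len(e.sequence) == 400 for e in pos + ctrl)

    def test_plant_count_within_binomial_bounds(self):
        truth = TruthManifest()
        cfg = SyntheticConfig(
            n_positives=1000, n_controls=10, seed=7,
            motif_plant_frequency=0.3, cooccur_plant_frequency=0.0,
        )
        plan = PlantPlan(singles=[("CREBLIKE", 0.3)])
        make_sequences(truth, cfg, plan=plan)
        n = len(truth.planted_motif_instances)
        lo, hi = scipy_stats.binom.interval(0.99, 1000, 0.3)
        assert lo <= n <= hi

    def test_all_plants_in_central_region(self):
        truth = TruthManifest()
        pos, _ = make_sequences(truth, self._plain_config())
        assert truth.planted_motif_instances  # something planted
        for _, name, start, _ in truth.planted_motif_instances:
            w = builtin_motifs()[name].shape[1]
            assert 50 <= start and start + w <= 350

    def test_pair_distance_bound(self):
        truth = TruthManifest()
        cfg = self._plain_config(cooccur_plant_frequency=1.0)
        make_sequences(truth, cfg)
        by_seq = {}
        for sid, name, start, _ in truth.planted_motif_instances:
            by_seq.setdefault(sid, {})[name] = start
        found = 0
        for sid, d in by_seq.items():
            if "SOXLIKE" in d and "SIXLIKE" in d:
                found += 1
                assert abs(d["SOXLIKE"] - d["SIXLIKE"]) <= cfg.cooccur_distance_bp
        assert found == cfg.n_positives

    def test_decoys_never_cooccur(self):
        truth = TruthManifest()
        cfg = self._plain_config(motif_plant_frequency=0.9)
        make_sequences(truth, cfg)
        by_seq = {}
        for sid, name, _, _ in truth.planted_motif_instances:
            by_seq.setdefault(sid, set()).add(name)
        for names in by_seq.values():
            assert not {"CREBLIKE", "ETSLIKE"} <= names

    def test_sequence_ids_encode_chromosome(self):
        truth = TruthManifest()
        pos, ctrl = make_sequences(truth, self._plain_config())
        for e in pos + ctrl:
            assert e.chrom in e.id

    def test_unknown_motif_rejected(self):
        with pytest.raises(KeyError):
            make_sequences(
                TruthManifest(),
                self._plain_config(),
                plan=PlantPlan(singles=[("NOPE", 0.5)]),
            )

    def test_fixture_motifs_high_information(self):
        for name, pwm in builtin_motifs().items():
            assert information_content(pwm) >= 10.0, name


class TestSimulateAll:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = SyntheticConfig(
            seed=5, n_positives=20, n_controls=25, n_genes=20,
            n_peaks_shared=30, n_peaks_emerging_per_celltype=5,
            n_cells_per_group=5,
        )
        for run in ("a", "b"):
            simulate_all(cfg, tmp_path / run)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_truth_manifest_conservation(self, tmp_path):
        """Counts in truth.json equal counts recoverable from emitted files."""
        from rretools.io import read_fasta, read_peaks_bed, read_tsv

        cfg = SyntheticConfig(
            seed=6, n_positives=30, n_controls=35, n_genes=20,
            n_peaks_shared=30, n_peaks_emerging_per_celltype=5,
            n_cells_per_group=5,
        )
        simulate_all(cfg, tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())

        for ct in cfg.cell_types:
            peaks = read_peaks_bed(tmp_path / f"peaks_treated_{ct}.bed")
            ids = {p.peak_id for p in peaks}
            for pid in truth["emerging_peak_ids"][ct]:
                assert pid in ids
        de = read_tsv(tmp_path / "de_genes.tsv")
        assert sorted(de["gene_id"]) == sorted(truth["de_gene_ids"])
        positives = read_fasta(tmp_path / "positives.fa")
        for sid, name, start, strand in truth["planted_motif_instances"]:
            assert sid in positives
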