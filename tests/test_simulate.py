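"""Simulator contracts: determinism, mechanism geometry, truth integrity."""

import numpy as np
import pandas as pd
import pytest

import intronerkit as ik
from intronerkit._seq import max_tandem_coverage, revcomp


def _bundle(seed=5, n_genes=80, length=250_000):
    return ik.simulate_genome(
        ik.GenomeSimConfig(n_chromosomes=1, chromosome_length=length,
                           n_genes=n_genes, seed=seed)
    )


class TestSimulateGenome:
    def test_zero_genes_gives_empty_annotation(self):
        b = ik.simulate_genome(
            ik.GenomeSimConfig(n_chromosomes=1, chromosome_length=10_000,
                               n_genes=0, seed=0)
        )
        assert b.genes == []
        assert b.genome_length == 10_000

    def test_realized_genic_fraction_tracks_request(self):
        b = ik.simulate_genome(
            ik.GenomeSimConfig(n_chromosomes=1, chromosome_length=1_000_000,
                               n_genes=300, genic_fraction=0.5, seed=3)
        )
        assert 0.45 <= ik.gene_density(b) <= 0.55

    def test_same_seed_byte_identical_output(self, tmp_path):
        paths = []
        for run in range(2):
            b = _bundle(seed=9, n_genes=30, length=60_000)
            fa, gff = tmp_path / f"r{run}.fa", tmp_path / f"r{run}.gff3"
            b.write_fasta(fa)
            b.write_gff3(gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_background_introns_canonical(self):
        b = _bundle()
        recs = ik.extract_introns(b)
        assert recs, "expected introns"
        assert all(r.seq[:2] == "GT" and r.seq[-2:] == "AG" for r in recs)

    def test_infeasible_config_raises(self):
        with pytest.raises(ValueError):
            ik.simulate_genome(
                ik.GenomeSimConfig(n_chromosomes=1, chromosome_length=20_000,
                                   n_genes=200, seed=0)
            )


class TestPlantFamily:
    def test_mechanism_d_elements_have_perfect_terminal_tir(self):
        b = _bundle(seed=6)
        spec = ik.FamilySpec(mechanism="D", tir_length=8, tsd_length=0,
                             copy_number=10, divergence=0.0)
        truth = ik.plant_family(b, spec, seed=1)
        assert len(truth) == 10
        for el in truth.element:
            assert el[:8] == revcomp(el[-8:])

    def test_mechanism_b_tsd_duplicated_at_equal_distances(self):
        b = _bundle(seed=6)
        spec = ik.FamilySpec(mechanism="B", tsd_length=4, tir_length=8,
                             copy_number=10, divergence=0.0)
        truth = ik.plant_family(b, spec, seed=2)
        for _, row in truth.iterrows():
            seq = b.sequences[row.chrom]
            if row.strand == "+":
                downstream = seq[row.end : row.end + 4]
            else:
                downstream = revcomp(seq[row.start - 4 : row.start])
            assert row.intron_seq[:4] == downstream == row.tsd

    def test_full_genic_bias_places_all_copies_in_genes(self):
        b = _bundle(seed=6)
        truth = ik.plant_family(
            b, ik.FamilySpec(mechanism="A", tsd_length=0, tir_length=0,
                             copy_number=8, genic_bias=1.0), seed=3
        )
        assert truth.genic.all()

    def test_truth_intervals_reproduce_planted_sequence(self):
        b = _bundle(seed=7)
        truth = ik.plant_family(
            b, ik.FamilySpec(mechanism="E", tsd_length=6, tir_length=0,
                             copy_number=12, genic_bias=0.7, divergence=0.0),
            seed=4,
        )
        for _, row in truth.iterrows():
            sub = b.sequences[row.chrom][row.start : row.end]
            if row.strand == "-":
                sub = revcomp(sub)
            assert sub == row.intron_seq

    def test_planted_introns_annotated_and_canonical(self):
        b = _bundle(seed=8)
        truth = ik.plant_family(
            b, ik.FamilySpec(mechanism="C", tsd_length=4, tir_length=0,
                             copy_number=10), seed=5
        )
        keys = {(r.chrom, r.start, r.end) for r in ik.extract_introns(b)}
        planted = set(zip(truth.chrom, truth.start, truth.end))
        assert planted <= keys
        assert all(s[:2] == "GT" and s[-2:] == "AG" for s in truth.intron_seq)

    def test_mechanism_f_adds_twelve_bases_to_mrna(self):
        b = _bundle(seed=9)
        genes_before = {g.id: g.cds_sequence(b.sequences) for g in b.genes}
        truth = ik.plant_family(
            b, ik.FamilySpec(mechanism="F", tsd_length=8, tir_length=0,
                             copy_number=5), seed=6
        )
        assert (truth.mrna_gain == 12).all()
        for gid in truth.gene_id:
            gene = next(g for g in b.genes if g.id == gid)
            after = gene.cds_sequence(b.sequences)
            assert len(after) == len(genes_before[gid]) + 12

    def test_mechanism_invariants_enforced(self):
        with pytest.raises(ValueError):
            ik.FamilySpec(mechanism="D", tir_length=4, tsd_length=0).validate()
        with pytest.raises(ValueError):
            ik.FamilySpec(mechanism="B", tsd_length=0).validate()
        with pytest.raises(ValueError):
            ik.FamilySpec(mechanism="C", tsd_length=4, tir_length=6).validate()


class TestConfounders:
    def test_all_zero_leaves_bundle_unchanged(self):
        b = _bundle(seed=10)
        seq_before = dict(b.sequences)
        n_genes = len(b.genes)
        conf = ik.add_confounders(b, 0, 0, 0, seed=1)
        assert len(conf) == 0
        assert b.sequences == seq_before and len(b.genes) == n_genes

    def test_paralog_pairs_are_high_identity_duplications(self):
        b = _bundle(seed=10)
        conf = ik.add_confounders(b, n_paralog_pairs=2, seed=1)
        assert len(conf) == 2
        genes = {g.id: g for g in b.genes}
        for _, row in conf.iterrows():
            p1 = genes[row.gene_id].protein(b.sequences)
            p2 = genes[row.partner].protein(b.sequences)
            assert len(p1) == len(p2)
            ident = sum(a == c for a, c in zip(p1, p2)) / len(p1)
            assert ident >= 0.90

    def test_microsat_introns_contain_interior_tandem_repeats(self):
        b = _bundle(seed=10)
        before = {(r.chrom, r.start, r.end) for r in ik.extract_introns(b)}
        conf = ik.add_confounders(b, n_microsat_introns=5, seed=2)
        recs = {(r.chrom, r.start, r.end): r for r in ik.extract_introns(b)}
        assert set(recs) == before  # replacement, not insertion
        for _, row in conf.iterrows():
            rec = recs[(row.chrom, row.start, row.end)]
            interior = rec.seq[15:-15]
            assert max_tandem_coverage(interior) * len(interior) >= 3 * 5
            # repeats do not reach within 15 nt of either boundary
            assert max_tandem_coverage(rec.seq[:15]) < 1.0

    def test_secondary_te_motif_shared_and_interior(self):
        b = _bundle(seed=10)
        conf = ik.add_confounders(b, n_secondary_te=5, seed=3)
        recs = {(r.chrom, r.start, r.end): r for r in ik.extract_introns(b)}
        motifs = []
        for _, row in conf.iterrows():
            rec = recs[(row.chrom, row.start, row.end)]
            motifs.append(rec.seq[20:70])
        assert len(set(motifs)) == 1 and len(motifs[0]) == 50


class TestSimulateCounts:
    def test_zero_expression_gives_zero_counts(self, small_bundle):
        cfg = ik.CountSimConfig(reads_per_kb=0.0, seed=1)
        counts, genes = ik.simulate_counts(small_bundle, None, cfg)
        assert (genes.reads == 0).all()
        cols = ["proper_splices", "missplices", "retained"]
        assert (counts[cols].to_numpy() == 0).all()

    def test_equal_retention_rates_indistinguishable(self):
        b = _bundle(seed=11, n_genes=120, length=400_000)
        truth = ik.plant_family(
            b, ik.FamilySpec(mechanism="A", tsd_length=0, tir_length=0,
                             copy_number=40), seed=1
        )
        cfg = ik.CountSimConfig(introner_retention_rate=0.08,
                                background_retention_rate=0.08, seed=2)
        counts, _ = ik.simulate_counts(b, truth, cfg)
        assert len(counts) >= 200
        grp = counts.groupby("is_introner")
        tot = grp[["retained", "proper_splices", "missplices"]].sum()
        frac = tot.retained / tot.sum(axis=1)
        n = tot.sum(axis=1).min()
        se = np.sqrt(0.08 * 0.92 / n)
        assert abs(frac[True] - frac[False]) < 3 * np.sqrt(2) * se

    def test_retention_rates_ordered_as_configured(self):
        b = _bundle(seed=11, n_genes=120, length=400_000)
        truth = ik.plant_family(
            b, ik.FamilySpec(mechanism="A", tsd_length=0, tir_length=0,
                             copy_number=100, genic_bias=1.0), seed=1
        )
        cfg = ik.CountSimConfig(introner_retention_rate=0.01,
                                background_retention_rate=0.10, seed=3)
        counts, _ = ik.simulate_counts(b, truth, cfg)
        assert counts.is_introner.sum() >= 100
        grp = counts.groupby("is_introner")
        tot = grp[["retained", "proper_splices", "missplices"]].sum()
        frac = tot.retained / tot.sum(axis=1)
        assert frac[True] < frac[False]

    def test_counts_deterministic_under_seed(self, small_bundle):
        cfg = ik.CountSimConfig(seed=9)
        c1, g1 = ik.simulate_counts(small_bundle, None, cfg)
        c2, g2 = ik.simulate_counts(small_bundle, None, cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(g1, g2)


class TestSpeciesPanel:
    def test_zero_rates_give_no_introner_flags(self):
        panel = ik.simulate_species_panel(10, 20, 0.0, 0.0, seed=1)
        assert not panel.introner_present.any()

    def test_cell_counts_near_binomial_expectation(self):
        panel = ik.simulate_species_panel(230, 1367, 0.17, 0.026, seed=2)
        t = ik.tabulate(panel)
        assert t.a + t.b == 230 and t.c + t.d == 1367
        # 3 sigma around expected cell counts
        assert abs(t.a - 230 * 0.17) <= 3 * np.sqrt(230 * 0.17 * 0.83)
        assert abs(t.c - 1367 * 0.026) <= 3 * np.sqrt(1367 * 0.026 * 0.974)

    def test_panel_deterministic(self):
        p1 = ik.simulate_species_panel(5, 5, 0.5, 0.5, seed=3)
        p2 = ik.simulate_species_panel(5, 5, 0.5, 0.5, seed=3)
        pd.testing.assert_frame_equal(p1, p2)
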