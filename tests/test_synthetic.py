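import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

import popomics as pm
from popomics.errors import ParameterError
from popomics.signatures import clr_transform, count_signature, gc_fraction
from popomics.synthetic import (
    CommunitySpec,
    PopulationSpec,
    fragment_into_contigs,
    generate_genome,
    inject_variants,
    simulate_spectra,
)

from conftest import truth_variant_keys


def _spec(**kw):
    base = dict(pop_id="p", genome_length=50_000, gc_fraction=0.5,
                signature_bias=1.0, relative_abundance=1.0)
    base.update(kw)
    return PopulationSpec(**base)


class TestGenerateGenome:
    def test_unbiased_baseline_gc(self):
        g = generate_genome(_spec(gc_fraction=0.5, signature_bias=0.0), seed=0)
        assert abs(gc_fraction(g) - 0.5) < 0.02

    @pytest.mark.parametrize("gc", [0.35, 0.65])
    def test_biased_chain_preserves_gc(self, gc):
        g = generate_genome(_spec(gc_fraction=gc, signature_bias=1.5), seed=3)
        assert abs(gc_fraction(g) - gc) < 0.02

    def test_seeded_determinism(self):
        s = _spec()
        assert generate_genome(s, seed=7) == generate_genome(s, seed=7)
        assert generate_genome(s, seed=7) != generate_genome(s, seed=8)

    def test_invalid_gc_rejected(self):
        with pytest.raises(ParameterError):
            _spec(gc_fraction=1.2)
        with pytest.raises(ParameterError):
            generate_genome(_spec(genome_length=5000), seed=0)

    def test_populations_separate_in_clr_space(self):
        # brute-force distance oracle: mean between-population CLR distance
        # must exceed the mean within-population distance
        law = {"name": "fixed", "length": 5000}
        clrs, labels = [], []
        for i, gc in enumerate([0.40, 0.65]):
            g = generate_genome(_spec(gc_fraction=gc, genome_length=100_000), seed=i)
            for frag in fragment_into_contigs(g, law, seed=i):
                clrs.append(clr_transform(count_signature(frag)))
                labels.append(i)
        X = np.vstack(clrs)
        lab = np.array(labels)
        d = cdist(X, X)
        same = lab[:, None] == lab[None, :]
        off_diag = ~np.eye(len(lab), dtype=bool)
        within = d[same & off_diag].mean()
        between = d[~same].mean()
        assert between > within


class TestFragmentation:
    def test_fixed_law_exact_tiling(self):
        frags = fragment_into_contigs("A" * 10_000, {"name": "fixed", "length": 1000},
                                      seed=0)
        assert len(frags) == 10
        assert all(len(f) == 1000 for f in frags)

    def test_minimum_length_and_conservation(self):
        g = generate_genome(_spec(), seed=2)
        frags = fragment_into_contigs(g, {"name": "loguniform", "min": 1000,
                                          "max": 20000}, seed=5)
        assert all(len(f) >= 500 for f in frags)
        assert all(len(f) >= 1000 for f in frags)   # law minimum
        assert "".join(frags) == g

    def test_law_validation(self):
        with pytest.raises(ParameterError):
            fragment_into_contigs("A" * 10_000, {"name": "fixed", "length": 400}, 0)
        with pytest.raises(ParameterError):
            fragment_into_contigs("A" * 600, {"name": "fixed", "length": 1000}, 0)
        with pytest.raises(ParameterError):
            fragment_into_contigs("A" * 10_000, {"name": "nope"}, 0)


class TestSimulateCounts:
    def test_library_totals_conserved_exactly(self, small_two_pop_bundle):
        b = small_two_pop_bundle
        assert b.metag_counts["count"].sum() == b.spec.total_metag_reads
        assert b.metat_counts["count"].sum() == b.spec.total_metat_reads

    def test_silent_population_has_zero_transcript_counts(self):
        spec = pm.two_population_community(seed=11, genome_length=100_000,
                                           total_metag_reads=50_000,
                                           total_metat_reads=50_000)
        spec.populations[0].expressed_fraction = 0.0
        b = pm.generate_community(spec)
        silent_genes = b.genes[b.genes["pop_id"] == "popA"]["gene_id"]
        counts = b.metat_counts.set_index("gene_id").loc[silent_genes, "count"]
        assert (counts == 0).all()

    def test_metagenomic_share_tracks_abundance(self):
        # binomial sampling oracle: pooled share of an 0.8-abundance
        # population is 0.8 within 3 s.e.
        spec = pm.two_population_community(seed=13, abundances=(0.8, 0.2),
                                           genome_length=100_000,
                                           total_metag_reads=1_000_000,
                                           total_metat_reads=10_000)
        b = pm.generate_community(spec)
        share = (b.metag_counts.merge(b.contigs[["contig_id", "pop_id"]],
                                      on="contig_id")
                 .groupby("pop_id")["count"].sum() / spec.total_metag_reads)
        se = np.sqrt(0.8 * 0.2 / spec.total_metag_reads)
        assert abs(share["popA"] - 0.8) < 3 * se

    def test_depth_definition(self, small_two_pop_bundle):
        b = small_two_pop_bundle
        merged = b.metag_counts.merge(b.depth, on="contig_id")
        expected = merged["count"] * b.spec.read_length / merged["length"]
        assert np.allclose(merged["depth"], expected)


class TestInjectVariants:
    def _contigs(self, seed=0):
        g = generate_genome(_spec(genome_length=100_000), seed=seed)
        frags = fragment_into_contigs(g, {"name": "fixed", "length": 5000}, seed)
        contigs = pd.DataFrame({
            "contig_id": [f"c{i}" for i in range(len(frags))],
            "length": [len(f) for f in frags],
        })
        return contigs, {f"c{i}": f for i, f in enumerate(frags)}

    def test_zero_rate_gives_empty_sets(self):
        contigs, seqs = self._contigs()
        truth, callsets = inject_variants(contigs, seqs, _spec(snp_per_kb=0.0), 1)
        assert len(truth) == 0
        assert all(len(df) == 0 for df in callsets.values())

    def test_variant_count_arithmetic(self):
        contigs, seqs = self._contigs()
        truth, _ = inject_variants(contigs, seqs, _spec(snp_per_kb=2.0), 1)
        assert len(truth) == 200     # 2/kb * 100 kb

    def test_zero_noise_callsets_equal_truth(self):
        contigs, seqs = self._contigs()
        truth, callsets = inject_variants(
            contigs, seqs, _spec(snp_per_kb=1.0), 2,
            caller_names=("x", "y", "z"), fp_rate=0.0, dropout_rate=0.0)
        truth_keys = set(map(tuple, truth[["contig", "pos", "ref", "alt"]].to_numpy()))
        for df in callsets.values():
            keys = set(map(tuple, df[["contig", "pos", "ref", "alt"]].to_numpy()))
            assert keys == truth_keys

    def test_ref_matches_sequence_and_alt_differs(self):
        contigs, seqs = self._contigs(seed=4)
        truth, _ = inject_variants(contigs, seqs, _spec(snp_per_kb=1.0), 5)
        for contig, pos, ref, alt in truth[["contig", "pos", "ref", "alt"]].itertuples(index=False):
            assert seqs[contig][pos - 1] == ref
            assert ref != alt


class TestSimulateSpectra:
    def _expressed(self, n=50):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "length_nt": 900,
            "level": 1.0,
        })

    def test_zero_detection_empty_table(self):
        ev = simulate_spectra(self._expressed(), _spec(proteome_detect_fraction=0.0), 1)
        assert len(ev) == 0

    def test_full_detection_covers_every_protein(self):
        ev = simulate_spectra(self._expressed(50), _spec(proteome_detect_fraction=1.0), 1)
        assert ev["protein_id"].nunique() == 50
        assert (ev["intensity"] > 0).all()


class TestCommunityInvariants:
    def test_abundances_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            CommunitySpec(populations=[
                _spec(pop_id="a", relative_abundance=0.6),
                _spec(pop_id="b", relative_abundance=0.6),
            ])

    def test_at_least_two_populations(self):
        with pytest.raises(ParameterError):
            CommunitySpec(populations=[_spec(relative_abundance=1.0)])

    def test_truth_tables_cover_every_entity_once(self, small_two_pop_bundle):
        b = small_two_pop_bundle
        assert set(b.truth.contig_to_pop) == set(b.contigs["contig_id"])
        assert sorted(b.truth.gene_truth["gene_id"]) == sorted(b.genes["gene_id"])
        assert not b.truth.gene_truth["gene_id"].duplicated().any()
        assert len(truth_variant_keys(b)) == len(b.truth.variant_truth)

    def test_contig_lengths_conserve_genome_length(self, small_two_pop_bundle):
        b = small_two_pop_bundle
        per_pop = b.contigs.groupby("pop_id")["length"].sum()
        for p in b.spec.populations:
            assert per_pop[p.pop_id] == p.genome_length

    def test_seeded_determinism_of_whole_bundle(self):
        spec = pm.two_population_community(seed=21, genome_length=60_000,
                                           total_metag_reads=20_000,
                                           total_metat_reads=20_000)
        a = pm.generate_community(spec)
        b = pm.generate_community(spec)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.metat_counts, b.metat_counts)
        pd.testing.assert_frame_equal(a.truth.variant_truth, b.truth.variant_truth)
        pd.testing.assert_frame_equal(a.protein_evidence, b.protein_evidence)
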