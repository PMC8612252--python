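"""Hypergeometric testing, BH adjustment and cross-genome domain selection."""

from fractions import Fraction
from math import comb

import pytest

import heliocontext as hc
from conftest import chain_contig, single_contig_genome


def exact_upper_tail(k, K, n, N):
    """Independent oracle: exact combinatorial sum in rational arithmetic."""
    total = Fraction(0)
    for j in range(k, min(n, K) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


def genome_with_domain_layout(n_genes, anchor_idx, domain_positions, accession="PFX"):
    """A single-contig genome; ``domain_positions`` carry the test domain."""
    domains = [
        (accession,) if i in domain_positions else () for i in range(n_genes)
    ]
    domains[anchor_idx] = domains[anchor_idx] + ("PF18761",)
    contig = chain_contig([50] * (n_genes - 1), ["+"] * n_genes, domains_per_gene=domains)
    return single_contig_genome(contig)


class TestHypergeometric:
    def test_zero_observed_gives_exactly_one(self):
        assert hc.hypergeometric_upper_tail(0, 5, 20, 100) == 1.0

    def test_domain_on_every_gene_gives_one(self):
        assert hc.hypergeometric_upper_tail(15, 30, 15, 30) == pytest.approx(1.0)

    def test_reference_case_matches_combinatorial_oracle(self):
        # N=30, K=6, n=20, k=5: exact value 2584/7917
        p = hc.hypergeometric_upper_tail(5, 6, 20, 30)
        assert p == pytest.approx(float(Fraction(2584, 7917)), abs=1e-12)
        assert p == pytest.approx(exact_upper_tail(5, 6, 20, 30), abs=1e-12)

    def test_small_grid_matches_oracle(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert hc.hypergeometric_upper_tail(k, K, n, N) == pytest.approx(
                            exact_upper_tail(k, K, n, N), abs=1e-12
                        )

    @pytest.mark.parametrize(
        "k,K,n,N", [(-1, 5, 10, 30), (6, 5, 10, 30), (2, 5, 40, 30), (2, 35, 10, 30)]
    )
    def test_bound_violations_are_hard_errors(self, k, K, n, N):
        with pytest.raises(ValueError):
            hc.hypergeometric_upper_tail(k, K, n, N)


class TestBenjaminiHochberg:
    def test_single_p_value_unchanged(self):
        assert hc.bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_computed_step_up_values(self):
        # q_i = min_{j>=i} p_(j) * m / j
        assert hc.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert hc.bh_adjust([0.01, 0.04, 0.03, 0.02]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        assert hc.bh_adjust([0.001, 0.1, 0.9]) == pytest.approx([0.003, 0.15, 0.9])

    def test_order_preserved_and_capped(self):
        q = hc.bh_adjust([0.9, 0.0001, 0.5])
        assert q[1] < q[2] <= q[0] <= 1.0

    def test_adjusted_never_below_raw(self):
        ps = [0.2, 0.01, 0.7, 0.03, 1.0, 0.5]
        assert all(qi >= pi for qi, pi in zip(hc.bh_adjust(ps), ps))

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1]])
    def test_out_of_range_p_is_hard_error(self, bad):
        with pytest.raises(ValueError):
            hc.bh_adjust(bad)


class TestEligibility:
    def test_ten_genes_each_side_is_eligible(self, config):
        genome = genome_with_domain_layout(21, 10, set())
        assert hc.eligible_loci([genome], config) == [("G1", "g11")]

    def test_nine_on_one_side_fails_both_requirement(self, config):
        genome = genome_with_domain_layout(40, 9, set())
        assert hc.eligible_loci([genome], config) == []

    def test_two_anchors_one_eligible(self, config):
        genome = genome_with_domain_layout(40, 20, set())
        # second, ineligible anchor near the edge
        for g in genome.iter_genes():
            if g.gene_id == "g3":
                g.domains.add(config.her_accession)
        assert hc.eligible_loci([genome], config) == [("G1", "g21")]


class TestNeighborhoodTests:
    def test_counts_match_spec_worked_example(self, config):
        # domain on 5 of the 20 neighbors and on one far gene: k=5, K=6, N=30
        positions = {10, 11, 12, 13, 14, 29}
        genome = genome_with_domain_layout(30, 15, positions)
        records = hc.test_neighborhood_domains(genome, "g16", config)
        rec = next(r for r in records if r.accession == "PFX")
        assert (rec.k, rec.K, rec.n, rec.N) == (5, 6, 20, 30)
        assert rec.p == pytest.approx(exact_upper_tail(5, 6, 20, 30), abs=1e-12)

    def test_domain_absent_from_neighborhood_not_reported(self, config):
        genome = genome_with_domain_layout(40, 20, {0, 39})
        records = hc.test_neighborhood_domains(genome, "g21", config)
        assert all(r.accession != "PFX" for r in records)

    def test_anchor_domains_excluded_from_k(self, config):
        genome = genome_with_domain_layout(30, 15, set())
        records = hc.test_neighborhood_domains(genome, "g16", config)
        # the anchor's own heliorhodopsin domain does not appear as a record
        assert all(r.accession != config.her_accession for r in records)

    def test_ineligible_locus_is_hard_error(self, config):
        genome = genome_with_domain_layout(15, 7, set())
        with pytest.raises(ValueError, match="not eligible"):
            hc.test_neighborhood_domains(genome, "g8", config)

    def test_planted_domain_has_smallest_p(self, config):
        genomes, truths = hc.generate_cohort(6, config, seed=42)
        for genome, truth in zip(genomes, truths):
            records = hc.test_neighborhood_domains(genome, truth.anchor_id, config)
            best = min(records, key=lambda r: r.p)
            assert best.accession == truth.planted_enriched_domains[0][0]


class TestSelection:
    def test_selection_fraction_arithmetic(self, config):
        genomes, _ = hc.generate_cohort(
            20, config, seed=7, enrichment_frac=0.15, with_proteins=False
        )
        records = hc.run_enrichment(genomes, config)
        summaries = hc.summarize_selection(records, genomes, config)
        by_acc = {s.accession: s for s in summaries}
        planted = by_acc["ENR001"]
        assert planted.n_genomes_eligible == 20
        assert planted.n_genomes_significant == 3
        assert planted.selected    # 3/20 = 0.15 >= 0.10

    def test_one_significant_genome_in_twenty_is_not_selected(self, config):
        genomes, _ = hc.generate_cohort(
            20, config, seed=8, enrichment_frac=0.05, with_proteins=False
        )
        records = hc.run_enrichment(genomes, config)
        by_acc = {s.accession: s for s in hc.summarize_selection(records, genomes, config)}
        planted = by_acc["ENR001"]
        assert planted.n_genomes_significant == 1
        assert not planted.selected

    def test_results_invariant_to_genome_order(self, config):
        genomes, _ = hc.generate_cohort(8, config, seed=9, with_proteins=False)
        fwd = hc.run_enrichment(genomes, config)
        rev = hc.run_enrichment(list(reversed(genomes)), config)
        assert fwd == rev

    def test_zero_eligible_genomes_is_hard_error(self, config):
        genome = genome_with_domain_layout(15, 7, set())
        with pytest.raises(ValueError, match="eligible"):
            hc.summarize_selection([], [genome], config)


class TestPerPhylum:
    def build_two_phylum_cohort(self, config):
        planted, _ = hc.generate_cohort(
            6, config, seed=31, phyla=("PhylumA",), enrichment_frac=1.0,
            with_proteins=False, genome_prefix="A",
        )
        null, _ = hc.generate_cohort(
            6, config, seed=32, phyla=("PhylumB",), enrichment_frac=0.0,
            with_proteins=False, genome_prefix="B",
        )
        return planted + null

    def test_enrichment_selected_only_in_planted_phylum(self, config):
        genomes = self.build_two_phylum_cohort(config)
        runs = hc.per_phylum_runs(genomes, config)
        assert set(runs) == {"PhylumA", "PhylumB"}
        selected_a = {s.accession for s in runs["PhylumA"] if s.selected}
        selected_b = {s.accession for s in runs["PhylumB"] if s.selected}
        assert "ENR001" in selected_a
        assert "ENR001" not in selected_b

    def test_phylum_below_five_genomes_omitted(self, config):
        genomes, _ = hc.generate_cohort(
            9, config, seed=33, phyla=("Big", "Big", "Small"), with_proteins=False
        )
        runs = hc.per_phylum_runs(genomes, config)
        assert "Big" in runs          # 6 genomes
        assert "Small" not in runs    # 3 genomes
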