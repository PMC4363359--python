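"""Screen simulator: planting, count tables, reads, evaluation."""

import numpy as np
import pytest

from tillseq import (
    CoverageModel,
    ErrorModel,
    EXPECTED,
    PlantedMutation,
    SAMPLED,
    WellAddress,
    Zygosity,
    build_scheme,
    evaluate_calls,
    plant_mutations,
    plant_singletons,
    simulate_counts,
    simulate_reads,
    synthetic_refs,
)
from tillseq.caller import VariantCandidate
from tillseq.pooling import Resolution
from tillseq.reference import barcode_table_for_scheme
from tillseq.simulate import SimTruth
from tillseq.tables import BASES

NO_ERROR = ErrorModel(
    mean_substitution_rate=0.0, background_indel_rate=0.0, homopolymer_indel_multiplier=0.0
)


def flat_coverage(mean):
    return CoverageModel(mean_coverage_per_pool=mean, pool_cv=0.0, end_dropoff_fraction=0.0)


def find_gc_position(ref, lo=10, hi=None):
    hi = hi or len(ref.sequence) - 10
    for i in range(lo, hi):
        if ref.sequence[i] in "GC":
            return i + 1  # 1-based
    raise AssertionError("no G/C site")


def het_singleton(scheme, ref, well=WellAddress(1, 1, 1), zygosity=Zygosity.HET):
    pos = find_gc_position(ref)
    ref_b = ref.sequence[pos - 1]
    alt_b = "A" if ref_b == "G" else "T"
    mut = PlantedMutation(well, ref.id, pos, ref_b, alt_b, zygosity)
    return plant_mutations(scheme, [ref], mutations=[mut], seed=0), mut


class TestPlanting:
    def test_explicit_single_mutation(self, small_scheme, one_amplicon):
        truth, mut = het_singleton(small_scheme, one_amplicon[0])
        assert truth.mutations == (mut,)

    def test_explicit_wrong_reference_base_rejected(self, small_scheme, one_amplicon):
        ref = one_amplicon[0]
        pos = find_gc_position(ref)
        wrong = "A" if ref.sequence[pos - 1] != "A" else "C"
        bad = PlantedMutation(WellAddress(1, 1, 1), ref.id, pos, wrong, "T", Zygosity.HET)
        with pytest.raises(ValueError):
            plant_mutations(small_scheme, [ref], mutations=[bad], seed=0)

    def test_zero_density_plants_nothing(self, small_scheme, one_amplicon):
        truth = plant_mutations(small_scheme, one_amplicon, density=0.0, seed=1)
        assert truth.mutations == ()

    def test_density_mode_matches_poisson_mean(self, one_amplicon):
        # 12 individuals x 200 bp at 1/300 bp: expected 8 mutations per run
        scheme = build_scheme(2, 2, 3)
        density = 1.0 / 300.0
        n_runs = 400
        counts = [
            len(plant_mutations(scheme, one_amplicon, density, seed=s).mutations)
            for s in range(n_runs)
        ]
        expected = scheme.population_size * 200 * density
        se = np.sqrt(expected / n_runs)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_ems_fraction_biases_to_transitions(self, one_amplicon):
        scheme = build_scheme(2, 2, 3)
        truth = plant_mutations(scheme, one_amplicon, density=1 / 50.0, seed=9)
        subs = [m.substitution for m in truth.mutations]
        assert len(subs) > 20
        ems = sum(s in ("G>A", "C>T") for s in subs)
        assert ems / len(subs) > 0.9

    def test_mutation_refbase_always_matches_reference(self, one_amplicon):
        scheme = build_scheme(2, 2, 3)
        truth = plant_mutations(scheme, one_amplicon, density=1 / 100.0, ems_fraction=0.5, seed=4)
        seq = one_amplicon[0].sequence
        for m in truth.mutations:
            assert seq[m.position - 1] == m.ref_base
            assert m.alt_base != m.ref_base

    def test_singletons_one_per_amplicon(self, small_scheme, two_amplicons):
        truth = plant_singletons(small_scheme, two_amplicons, seed=5)
        assert len(truth.mutations) == 2
        assert {m.amplicon_id for m in truth.mutations} == {"amp1", "amp2"}
        assert all(m.is_ems_type for m in truth.mutations)

    def test_truth_tsv_roundtrip(self, tmp_path, small_scheme, two_amplicons):
        truth = plant_singletons(small_scheme, two_amplicons, seed=5)
        truth.write(tmp_path / "truth.tsv")
        back = SimTruth.read(tmp_path / "truth.tsv")
        assert back.mutations == truth.mutations
        assert (back.n_plates, back.n_rows, back.n_cols) == (2, 2, 3)


class TestSimulateCountsExpected:
    def test_hom_singleton_closed_form(self, one_amplicon):
        # a homozygote in a 96-member pool at 5000x: 5000/96 -> 52 alt reads
        scheme = build_scheme(1, 8, 12)
        truth, mut = het_singleton(scheme, one_amplicon[0], zygosity=Zygosity.HOM)
        counts = simulate_counts(
            scheme, truth, one_amplicon, flat_coverage(5000), NO_ERROR, EXPECTED, 0
        )
        row = counts[(counts.pool == "A1") & (counts.position == mut.position)].iloc[0]
        assert row[mut.alt_base] == 52
        assert row[[*BASES, "ins", "del"]].sum() == 5000

    def test_het_fraction_exact(self, one_amplicon):
        scheme = build_scheme(1, 8, 12)
        truth, mut = het_singleton(scheme, one_amplicon[0])
        counts = simulate_counts(
            scheme, truth, one_amplicon, flat_coverage(1920), NO_ERROR, EXPECTED, 0
        )
        row = counts[(counts.pool == "A1") & (counts.position == mut.position)].iloc[0]
        assert row[mut.alt_base] / row[BASES].sum() == pytest.approx(1 / 192)

    def test_elevation_in_exactly_three_pools(self, small_scheme, one_amplicon):
        truth, mut = het_singleton(small_scheme, one_amplicon[0], WellAddress(2, 1, 3))
        counts = simulate_counts(
            small_scheme, truth, one_amplicon, flat_coverage(4000), NO_ERROR, EXPECTED, 0
        )
        at_pos = counts[counts.position == mut.position]
        elevated = set(at_pos[at_pos[mut.alt_base] > 0].pool)
        assert elevated == {"A2", "B3", "C1"}

    def test_deterministic_for_any_seed(self, small_scheme, one_amplicon):
        truth, _ = het_singleton(small_scheme, one_amplicon[0])
        a = simulate_counts(small_scheme, truth, one_amplicon, mode=EXPECTED, seed=1)
        b = simulate_counts(small_scheme, truth, one_amplicon, mode=EXPECTED, seed=2)
        assert a.equals(b)


class TestSimulateCountsSampled:
    def test_count_conservation_within_pool(self, small_scheme, one_amplicon):
        truth, _ = het_singleton(small_scheme, one_amplicon[0])
        cov = CoverageModel(mean_coverage_per_pool=800, pool_cv=0.5, end_dropoff_fraction=0.0)
        counts = simulate_counts(small_scheme, truth, one_amplicon, cov, mode=SAMPLED, seed=3)
        totals = counts[[*BASES, "ins", "del"]].sum(axis=1)
        per_pool = counts.assign(total=totals).groupby("pool")["total"].nunique()
        # flat profile: every position of a pool carries that pool's coverage
        assert (per_pool == 1).all()

    def test_seed_reproducibility(self, small_scheme, one_amplicon):
        truth, _ = het_singleton(small_scheme, one_amplicon[0])
        a = simulate_counts(small_scheme, truth, one_amplicon, mode=SAMPLED, seed=11)
        b = simulate_counts(small_scheme, truth, one_amplicon, mode=SAMPLED, seed=11)
        c = simulate_counts(small_scheme, truth, one_amplicon, mode=SAMPLED, seed=12)
        assert a.equals(b)
        assert not a.equals(c)

    def test_sampled_mean_matches_binomial_expectation(self, one_amplicon):
        # HET carrier in a 96-pool at 4000x, error-free: mean frequency ~ 1/192
        scheme = build_scheme(1, 8, 12)
        ref = synthetic_refs(1, 60, seed=2)[0]
        truth, mut = het_singleton(scheme, ref)
        cov = flat_coverage(4000)
        n_reps = 300
        freqs = []
        for s in range(n_reps):
            counts = simulate_counts(scheme, truth, [ref], cov, NO_ERROR, SAMPLED, s)
            row = counts[(counts.pool == "A1") & (counts.position == mut.position)].iloc[0]
            freqs.append(row[mut.alt_base] / row[BASES].sum())
        p = 1 / 192
        se = np.sqrt(p * (1 - p) / 4000 / n_reps)
        assert abs(np.mean(freqs) - p) < 3 * se

    def test_homopolymer_positions_attract_indels(self):
        scheme = build_scheme(1, 2, 2)
        ref = synthetic_refs(1, 40, seed=1)[0]
        seq = ref.sequence[:20] + "GGGGG" + ref.sequence[25:]
        ref = type(ref)(ref.id, seq, ref.forward_primer, ref.reverse_primer)
        truth = plant_mutations(scheme, [ref], density=0.0, seed=0)
        err = ErrorModel(mean_substitution_rate=0.002, background_indel_rate=0.0)
        counts = simulate_counts(scheme, truth, [ref], flat_coverage(20000), err, SAMPLED, 5)
        from tillseq.reference import homopolymer_mask

        mask = homopolymer_mask(seq, err.homopolymer_min_run)
        in_run = counts.position.map(lambda p: bool(mask[p - 1]))
        assert counts.loc[in_run, ["ins", "del"]].to_numpy().sum() > 0
        assert counts.loc[~in_run, ["ins", "del"]].to_numpy().sum() == 0


class TestSimulateReads:
    def test_seed_reproducibility_bytes(self, tmp_path, two_amplicons):
        scheme = build_scheme(1, 2, 2)
        truth = plant_singletons(scheme, two_amplicons, seed=3)
        barcodes = barcode_table_for_scheme(scheme, seed=1)
        cov = CoverageModel(mean_coverage_per_pool=25, junk_read_fraction=0.1)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_reads(scheme, truth, two_amplicons, barcodes, cov, seed=9, out_path=p1)
        simulate_reads(scheme, truth, two_amplicons, barcodes, cov, seed=9, out_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_junk_reads_all_barcoded(self, tmp_path, two_amplicons):
        scheme = build_scheme(1, 2, 2)
        truth = plant_mutations(scheme, two_amplicons, density=0.0, seed=0)
        barcodes = barcode_table_for_scheme(scheme, seed=1)
        cov = CoverageModel(mean_coverage_per_pool=20, junk_read_fraction=0.0, end_dropoff_fraction=0.0)
        path = tmp_path / "r.fastq"
        simulate_reads(scheme, truth, two_amplicons, barcodes, cov, NO_ERROR, 4, path)
        valid = set(barcodes.barcodes.values())
        lines = path.read_text().splitlines()
        seqs = lines[1::4]
        assert seqs
        assert all(s[:10] in valid for s in seqs)

    def test_all_junk_run_has_no_barcoded_reads(self, tmp_path, two_amplicons):
        scheme = build_scheme(1, 2, 2)
        truth = plant_mutations(scheme, two_amplicons, density=0.0, seed=0)
        barcodes = barcode_table_for_scheme(scheme, seed=1)
        cov = CoverageModel(mean_coverage_per_pool=20, junk_read_fraction=1.0)
        path = tmp_path / "junk.fastq"
        summary = simulate_reads(scheme, truth, two_amplicons, barcodes, cov, NO_ERROR, 4, path)
        assert summary["n_real"] == 0
        assert summary["n_junk"] > 0
        valid = set(barcodes.barcodes.values())
        seqs = path.read_text().splitlines()[1::4]
        assert all(s[:10] not in valid for s in seqs)

    def test_missing_barcode_rejected(self, tmp_path, two_amplicons):
        scheme = build_scheme(1, 2, 2)
        truth = plant_mutations(scheme, two_amplicons, density=0.0, seed=0)
        barcodes = barcode_table_for_scheme(build_scheme(1, 2, 1), seed=1)  # too few pools
        with pytest.raises(ValueError):
            simulate_reads(
                scheme, truth, two_amplicons, barcodes, CoverageModel(mean_coverage_per_pool=5),
                seed=0, out_path=tmp_path / "x.fastq",
            )


def make_candidate(amplicon, position, ref, alt, wells, tier=99):
    res = Resolution.INDIVIDUAL if len(wells) == 1 else Resolution.SUBSET
    return VariantCandidate(
        amplicon_id=amplicon, position=position, ref=ref, alt=alt, pools={},
        wells=frozenset(wells), resolution=res, tier=tier,
        ems_consistent=f"{ref}>{alt}" in ("G>A", "C>T"),
    )


class TestEvaluateCalls:
    def _truth(self, scheme, mutations):
        return SimTruth(tuple(mutations), 0, scheme.n_plates, scheme.n_rows, scheme.n_cols)

    def test_empty_truth_empty_calls(self, small_scheme):
        report = evaluate_calls(self._truth(small_scheme, []), [])
        assert (report.true_positives, report.false_positives, report.false_negatives) == (0, 0, 0)
        assert report.individual_accuracy == 0.0

    def test_perfect_call(self, small_scheme):
        m = PlantedMutation(WellAddress(1, 2, 3), "amp1", 10, "G", "A", Zygosity.HET)
        report = evaluate_calls(
            self._truth(small_scheme, [m]),
            [make_candidate("amp1", 10, "G", "A", [m.well])],
        )
        assert (report.true_positives, report.false_positives, report.false_negatives) == (1, 0, 0)
        assert report.individual_accuracy == 1.0
        assert report.recall == 1.0

    def test_wrong_position_is_fp_plus_fn(self, small_scheme):
        m = PlantedMutation(WellAddress(1, 2, 3), "amp1", 10, "G", "A", Zygosity.HET)
        report = evaluate_calls(
            self._truth(small_scheme, [m]),
            [make_candidate("amp1", 11, "G", "A", [m.well])],
        )
        assert (report.true_positives, report.false_positives, report.false_negatives) == (0, 1, 1)

    def test_subset_candidate_counts_tp_but_not_exact(self, small_scheme):
        m = PlantedMutation(WellAddress(1, 2, 3), "amp1", 10, "G", "A", Zygosity.HET)
        wells = [m.well, WellAddress(2, 2, 3)]
        report = evaluate_calls(
            self._truth(small_scheme, [m]),
            [make_candidate("amp1", 10, "G", "A", wells, tier=85)],
        )
        assert report.true_positives == 1
        assert report.individual_accuracy == 0.0
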