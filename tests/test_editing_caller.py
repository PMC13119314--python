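import numpy as np
import pytest

from oracles import oracle_call_events
from conftest import make_single_exon_models, random_site_tables

from rlpkit.editing_caller import (
    CallerParams, call_events, genomic_edit_bases, mutation_spectrum,
)
from rlpkit.transcript_io import SiteCount, TranscriptModel


def site(contig, pos, ref, **bases):
    counts = {b: 0 for b in "ACGT"}
    counts.update(bases)
    return SiteCount(contig, pos, ref, counts)


def _events_as_tuples(events):
    return {(e.gene_id, e.contig, e.position, e.alt_count, e.depth)
            for e in events}


@pytest.fixture
def one_gene():
    return [TranscriptModel("g1", "g1.t", "c1", "+", ((0, 1000),))]


class TestFilters:
    def test_three_qualifying_sites_called(self, one_gene):
        """Three clean A>G sites on one transcript pass all four filters."""
        induced = [site("c1", p, "A", A=47, G=5) for p in (10, 20, 30)]
        controls = [[site("c1", p, "A", A=50) for p in (10, 20, 30)]]
        events = call_events(induced, controls, one_gene)
        assert len(events) == 3
        assert {e.conversion for e in events} == {"A>G"}
        assert events[0].editing_ratio == pytest.approx(5 / 52)

    def test_control_signal_blocks_site(self, one_gene):
        induced = [site("c1", p, "A", A=47, G=5) for p in (10, 20, 30)]
        controls = [[site("c1", 10, "A", A=49, G=1),
                     site("c1", 20, "A", A=50),
                     site("c1", 30, "A", A=50)]]
        events = call_events(induced, controls, one_gene)
        # site 10 fails the control filter; only 2 remain -> transcript floor
        assert events == []

    def test_two_snv_types_blocked(self, one_gene):
        induced = [site("c1", 10, "A", A=44, G=3, C=3)] + \
            [site("c1", p, "A", A=47, G=5) for p in (20, 30, 40)]
        controls = [[site("c1", p, "A", A=50) for p in (10, 20, 30, 40)]]
        events = call_events(induced, controls, one_gene)
        assert {e.position for e in events} == {20, 30, 40}

    def test_per_transcript_floor(self, one_gene):
        induced = [site("c1", p, "A", A=47, G=5) for p in (10, 20)]
        controls = [[site("c1", p, "A", A=50) for p in (10, 20)]]
        assert call_events(induced, controls, one_gene) == []

    def test_low_ratio_events_do_not_count_toward_floor(self, one_gene):
        # ratio 5/600 < 0.01: qualifies on support but not on ratio
        induced = [site("c1", 10, "A", A=595, G=5)] + \
            [site("c1", p, "A", A=47, G=5) for p in (20, 30)]
        controls = [[site("c1", p, "A", A=600 if p == 10 else 50)
                     for p in (10, 20, 30)]]
        assert call_events(induced, controls, one_gene) == []

    def test_missing_control_policy(self, one_gene):
        induced = [site("c1", p, "A", A=47, G=5) for p in (10, 20, 30)]
        assert call_events(induced, [[]], one_gene) == []
        accept = CallerParams(missing_control_policy="accept")
        assert len(call_events(induced, [[]], one_gene, accept)) == 3

    def test_minus_strand_reports_transcript_orientation(self):
        """Genomic T>C on a minus-strand gene is an A>G edit."""
        models = [TranscriptModel("g1", "g1.t", "c1", "-", ((0, 1000),))]
        induced = [site("c1", p, "T", T=47, C=5) for p in (10, 20, 30)]
        controls = [[site("c1", p, "T", T=50) for p in (10, 20, 30)]]
        events = call_events(induced, controls, models)
        assert len(events) == 3
        assert all(e.conversion == "A>G" and e.strand == "-" for e in events)

    def test_zero_depth_site_skipped(self, one_gene):
        induced = [site("c1", 10, "A")] + \
            [site("c1", p, "A", A=47, G=5) for p in (20, 30, 40)]
        controls = [[site("c1", p, "A", A=50) for p in (10, 20, 30, 40)]]
        events = call_events(induced, controls, one_gene)
        assert {e.position for e in events} == {20, 30, 40}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_random_tables_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        models = make_single_exon_models(6)
        induced, controls, site_gene = random_site_tables(rng, models, 200)
        params = CallerParams(
            min_alt=int(rng.integers(1, 5)),
            min_events_per_transcript=int(rng.integers(1, 4)),
            min_event_ratio=float(rng.choice([0.0, 0.01, 0.05])),
            control_max_alt=int(rng.integers(0, 3)),
            purity_min_fraction=float(rng.choice([0.5, 0.9, 1.0])),
        )
        got = _events_as_tuples(call_events(induced, controls, models, params))
        expected = oracle_call_events(induced, controls, site_gene, params, "A>G")
        assert got == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_monotonicity_in_thresholds(self, seed):
        """Raising min_alt or min_event_ratio never adds events."""
        rng = np.random.default_rng(100 + seed)
        models = make_single_exon_models(6)
        induced, controls, _ = random_site_tables(rng, models, 150)
        base = _events_as_tuples(
            call_events(induced, controls, models, CallerParams(min_alt=2)))
        stricter = _events_as_tuples(
            call_events(induced, controls, models, CallerParams(min_alt=4)))
        assert stricter <= base
        loose = _events_as_tuples(call_events(
            induced, controls, models, CallerParams(min_event_ratio=0.0)))
        tight = _events_as_tuples(call_events(
            induced, controls, models, CallerParams(min_event_ratio=0.05)))
        assert tight <= loose

    def test_strand_mirroring_gives_identical_events(self):
        """Reverse-complementing the dataset to the minus strand leaves the
        event list identical in transcript coordinates."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(7)
        plus = make_single_exon_models(4, strand_cycle=("+",))
        induced, controls, _ = random_site_tables(rng, plus, 150)
        minus = [TranscriptModel(m.gene_id, m.transcript_id, m.contig, "-",
                                 m.exons) for m in plus]

        def mirror(sites):
            return [SiteCount(s.contig, s.position, comp[s.ref_base],
                              {comp[b]: n for b, n in s.counts.items()})
                    for s in sites]

        ev_plus = call_events(induced, controls, plus)
        ev_minus = call_events(mirror(induced), [mirror(c) for c in controls],
                               minus)
        key = lambda evs: {(e.gene_id, e.position, e.conversion, e.alt_count)
                           for e in evs}
        assert key(ev_plus) == key(ev_minus)


class TestPlantedRecovery:
    def test_recall_and_precision_on_clean_synthetic_data(self, bulk_sim, small_transcriptome):
        """With zero control noise, every planted site meeting the
        thresholds is called and nothing else is."""
        truth, sim = bulk_sim
        models, _ = small_transcriptome
        params = CallerParams()
        events = call_events(sim.induced, sim.controls, models,
                             params, truth.chemistry)
        called = {(e.contig, e.position) for e in events}
        qual = sim.planted[
            (sim.planted.alt_count >= params.min_alt)
            & (sim.planted.alt_count / sim.planted.depth > params.min_event_ratio)
        ]
        per_gene = qual.groupby("gene_id").size()
        expected = {
            (r.contig, r.position) for r in qual.itertuples()
            if per_gene[r.gene_id] >= params.min_events_per_transcript
        }
        assert called == expected


class TestMutationSpectrum:
    def test_fractions(self):
        spectrum = mutation_spectrum(["A>G"] * 9 + ["C>T"])
        assert spectrum["A>G"] == pytest.approx(0.9)
        assert spectrum["C>T"] == pytest.approx(0.1)
        assert spectrum.sum() == pytest.approx(1.0)
        assert len(spectrum) == 12

    def test_single_class(self):
        spectrum = mutation_spectrum(["G>C", "G>C"])
        assert spectrum["G>C"] == 1.0 and spectrum.drop("G>C").eq(0).all()

    def test_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            mutation_spectrum([])


def test_genomic_edit_bases_strand_flip():
    assert genomic_edit_bases("A>G", "+") == ("A", "G")
    assert genomic_edit_bases("A>G", "-") == ("T", "C")
    assert genomic_edit_bases("C>T", "-") == ("G", "A")
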