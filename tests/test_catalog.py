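"""Catalog construction: pure-run detection, merging, uniqueness keys."""

import numpy as np
import pytest

from ebml.catalog import (CatalogConfig, PureRun, catalog_to_frame,
                          deduplicate_catalog, find_pure_repeats,
                          merge_and_filter, min_rotation, scan_reference,
                          uniqueness_key)
from ebml.simulate import simulate_reference, write_fasta


def oracle_pure_runs(seq, cfg):
    """Brute-force oracle: every maximal tandem interval, found by direct
    per-position extension, independent of the production scanner."""
    n = len(seq)
    found = set()
    for p in range(cfg.min_unit, cfg.max_unit + 1):
        for start in range(n - p):
            unit = seq[start:start + p]
            if "N" in unit:
                continue
            # primitive unit only
            if any(p % q == 0 and unit == unit[:q] * (p // q)
                   for q in range(1, p)):
                continue
            end = start + p
            while end < n and seq[end] == seq[end - p] and seq[end] != "N":
                end += 1
            # maximal on the left
            if start > 0 and seq[start - 1] == seq[start + p - 1] \
                    and seq[start - 1] != "N":
                continue
            if (end - start) // p < cfg.min_copies(p):
                continue
            found.add((start, end, min_rotation(unit)))
    return sorted(found)


class TestFindPureRepeats:
    def test_mononucleotide_run_with_short_prefix(self):
        cfg = CatalogConfig()
        runs = find_pure_repeats("TTTAAAAAAAAGG", cfg)
        assert [(r.start, r.end, r.unit) for r in runs] == [(3, 11, "A")]

    def test_empty_sequence(self):
        assert find_pure_repeats("", CatalogConfig()) == []

    def test_dinucleotide_no_phase_duplicate(self):
        runs = find_pure_repeats("ACACACACAC", CatalogConfig())
        assert [(r.start, r.end, r.unit) for r in runs] == [(0, 10, "AC")]

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            find_pure_repeats("ACGTX", CatalogConfig())

    def test_n_terminates_runs(self):
        runs = find_pure_repeats("AAAAAAANAAAAAAA", CatalogConfig())
        assert [(r.start, r.end, r.unit) for r in runs] == \
            [(0, 7, "A"), (8, 15, "A")]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        cfg = CatalogConfig()
        rng = np.random.default_rng(seed)
        # biased alphabet so tandem runs actually occur
        seq = "".join(rng.choice(["A", "C", "G", "T"], size=400,
                                 p=[0.4, 0.3, 0.2, 0.1]))
        got = sorted((r.start, r.end, r.unit) for r in find_pure_repeats(seq, cfg))
        assert got == oracle_pure_runs(seq, cfg)


class TestMergeAndFilter:
    cfg = CatalogConfig()

    def _runs(self, spans):
        return [PureRun(s, e, u, u) for s, e, u in spans]

    def test_small_gap_merges_same_unit(self):
        seq = "AAAAAA" + "GTC" + "AAAAA" + "G" * 10
        loci = merge_and_filter(self._runs([(0, 6, "A"), (9, 14, "A")]),
                                self.cfg, seq)
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.is_compound) == (0, 14, False)
        assert l.segments == [(0, 6, "A"), (9, 14, "A")]

    def test_gap_over_threshold_splits(self):
        seq = "AAAAAA" + "GTCGTCGTCGT"[:11] + "AAAAA" + "G" * 10
        loci = merge_and_filter(self._runs([(0, 6, "A"), (17, 22, "A")]),
                                self.cfg, seq)
        # each piece is under min_array_len on its own: 6 bp and 5 bp
        assert loci == []
        big = merge_and_filter(self._runs([(0, 9, "A"), (20, 28, "A")]),
                               self.cfg, "A" * 9 + "GTCGTCGTCGT" + "A" * 8 + "G" * 9)
        assert [(l.start, l.end) for l in big] == [(0, 9), (20, 28)]

    def test_different_units_make_compound(self):
        seq = "AAAAAA" + "GT" + "AGAGAGAG" + "C" * 10
        loci = merge_and_filter(self._runs([(0, 6, "A"), (8, 16, "AG")]),
                                self.cfg, seq)
        assert len(loci) == 1
        assert loci[0].is_compound
        assert loci[0].unit == "AG"  # longest segment's motif

    def test_edge_locus_flagged(self):
        seq = "AAAAAAAA" + "GCGTC"
        loci = merge_and_filter(self._runs([(0, 8, "A")]), self.cfg, seq)
        assert loci[0].edge_truncated and not loci[0].hashable

    def test_merge_gap_monotonicity(self):
        """A larger merge gap can only merge more runs, never fewer.

        Measured with min_array_len neutralized, since the length filter can
        otherwise rescue short runs into a newly merged locus."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(["A", "C", "G", "T"], size=600,
                                 p=[0.45, 0.3, 0.15, 0.1]))
        counts = []
        for gap in (0, 5, 10, 20, 40):
            cfg = CatalogConfig(merge_gap=gap, min_array_len=1)
            runs = find_pure_repeats(seq, cfg)
            counts.append(len(merge_and_filter(runs, cfg, seq)))
        assert counts == sorted(counts, reverse=True)


class TestUniquenessKey:
    def _locus(self, up, unit, down, copies):
        seq = up + unit * copies + down
        cfg = CatalogConfig()
        runs = find_pure_repeats(seq, cfg)
        loci = merge_and_filter(runs, cfg, seq)
        assert len(loci) == 1
        return loci[0], cfg

    def test_worked_example_long_array(self):
        locus, cfg = self._locus("GCTGC", "A", "CTTAG", 34)
        assert uniqueness_key(locus, cfg) == "GCTGCACTTAG"

    def test_key_independent_of_array_length(self):
        l34, cfg = self._locus("GCTGC", "A", "CTTAG", 34)
        l15, _ = self._locus("GCTGC", "A", "CTTAG", 15)
        assert uniqueness_key(l34, cfg) == uniqueness_key(l15, cfg)

    def test_dinucleotide_key_concatenation(self):
        locus, cfg = self._locus("AAGCA", "AC", "GGGTG", 7)
        assert uniqueness_key(locus, cfg) == "AAGCAACGGGTG"

    def test_edge_locus_refuses_key(self):
        cfg = CatalogConfig()
        seq = "AAAAAAAAAA" + "GCGTC"
        loci = merge_and_filter(find_pure_repeats(seq, cfg), cfg, seq)
        with pytest.raises(ValueError):
            uniqueness_key(loci[0], cfg)


class TestDeduplicate:
    def _catalog(self, seq):
        cfg = CatalogConfig()
        return merge_and_filter(find_pure_repeats(seq, cfg), cfg, seq), cfg

    def test_colliding_pair_both_removed(self):
        from ebml.simulate import square_free_word

        spacer = square_free_word(40)
        seq = ("TTGCA" + "GCTGC" + "A" * 34 + "CTTAG" + spacer
               + "GCTGC" + "A" * 15 + "CTTAG" + "TTGCA")
        loci, cfg = self._catalog(seq)
        polyA = [l for l in loci if l.unit == "A"]
        assert len(polyA) == 2
        retained, removed = deduplicate_catalog(loci, cfg)
        assert all(l.unit != "A" for l in retained)
        assert {l.start for l in removed} == {l.start for l in polyA}

    def test_distinct_keys_all_retained(self):
        seq = "CTGAC" + "A" * 10 + "GTCCA" + "TT" + "AG" * 5 + "CCATG" + "GGTCA"
        loci, cfg = self._catalog(seq)
        retained, removed = deduplicate_catalog(loci, cfg)
        assert removed == [] and len(retained) == len([l for l in loci if l.hashable])

    def test_triple_collision_drops_all_three(self):
        from ebml.catalog import RepeatLocus

        def mk(i, up, down):
            return RepeatLocus(f"L{i}", "c", 100 * i, 100 * i + 10, "A", 1,
                               "A" * 10, [(100 * i, 100 * i + 10, "A")], False,
                               up, down)
        loci = [mk(0, "GCTGC", "CTTAG"), mk(1, "GCTGC", "CTTAG"),
                mk(2, "GCTGC", "CTTAG"), mk(3, "AAACC", "GGTTT"),
                mk(4, "CCCAA", "TTGGA")]
        retained, removed = deduplicate_catalog(loci, CatalogConfig())
        assert len(retained) == 2 and len(removed) == 3

    def test_idempotent(self):
        from ebml.simulate import square_free_word

        spacer = square_free_word(40)
        seq = ("TTGCA" + "GCTGC" + "A" * 34 + "CTTAG" + spacer
               + "GCTGC" + "A" * 15 + "CTTAG" + "TTGCA")
        loci, cfg = self._catalog(seq)
        once, _ = deduplicate_catalog(loci, cfg)
        twice, removed2 = deduplicate_catalog(once, cfg)
        assert twice == once and removed2 == []
        keys = [uniqueness_key(l, cfg) for l in once]
        assert len(keys) == len(set(keys))


class TestScanReference:
    def test_array_seq_round_trip(self):
        cfg = CatalogConfig()
        records, _ = simulate_reference(15, 8000, cfg, seed=3)
        seq = records["chrSim1"]
        loci = merge_and_filter(find_pure_repeats(seq, cfg), cfg, seq)
        for l in loci:
            assert l.array_seq == seq[l.start:l.end]

    def test_scan_matches_planted_truth(self, tmp_path):
        cfg = CatalogConfig()
        records, truth = simulate_reference(20, 10000, cfg, seed=7)
        fasta = tmp_path / "ref.fa"
        write_fasta(records, fasta)
        df = scan_reference(fasta, cfg)
        want = truth[~truth["expect_removed"]]
        assert list(df["start"]) == list(want["start"])
        assert list(df["end"]) == list(want["end"])
        assert list(df["unit"]) == list(want["unit"])

    def test_scan_deterministic(self, tmp_path):
        records, _ = simulate_reference(10, 6000, seed=1)
        fasta = tmp_path / "ref.fa"
        write_fasta(records, fasta)
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        scan_reference(fasta, out_path=out1)
        scan_reference(fasta, out_path=out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_all_n_fasta_empty_catalog(self, tmp_path):
        fasta = tmp_path / "n.fa"
        fasta.write_text(">c1\n" + "N" * 200 + "\n")
        assert len(scan_reference(fasta)) == 0

    def test_missing_fasta_errors(self, tmp_path):
        with pytest.raises(Exception):
            scan_reference(tmp_path / "absent.fa")
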