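"""Probe designer: sequence primitives, window selection, pair assembly."""

import io

import numpy as np
import pytest

from hcrkit.probe_design import (
    DEFAULT_PARAMS,
    PLACEHOLDER_AMPLIFIERS,
    Amplifier,
    DesignParams,
    ProbeWindow,
    TargetGene,
    assemble_pair,
    design_panel,
    design_probe_set,
    enumerate_windows,
    load_targets,
    max_homopolymer,
    revcomp,
)
from hcrkit.simulate import synth_transcriptome, write_fasta

from conftest import random_seq

B1 = PLACEHOLDER_AMPLIFIERS["B1"]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_oracle(seq):
    # independent character-wise reverse complement
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def max_run_oracle(seq):
    # brute-force run-length scan
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


class TestPrimitives:
    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT")])
    def test_revcomp_examples(self, seq, expected):
        assert revcomp(seq) == expected

    def test_revcomp_involution_matches_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = random_seq(rng, 52)
            assert revcomp(s) == revcomp_oracle(s)
            assert revcomp(revcomp(s)) == s

    def test_revcomp_rejects_invalid(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")

    @pytest.mark.parametrize("seq,expected", [("ACGT", 1), ("AAACCCCG", 4)])
    def test_max_homopolymer_examples(self, seq, expected):
        assert max_homopolymer(seq) == expected

    def test_max_homopolymer_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            s = random_seq(rng, 45)
            assert max_homopolymer(s) == max_run_oracle(s)

    def test_max_homopolymer_empty_raises(self):
        with pytest.raises(ValueError):
            max_homopolymer("")


class TestLoadTargets:
    def test_two_records_order_preserved(self):
        fasta = io.StringIO(">A1 gx\nACGTACGT\n>A2 gy\nTTTTCCCC\n")
        targets, rejected = load_targets(fasta)
        assert [t.accession for t in targets] == ["A1", "A2"]
        assert [t.symbol for t in targets] == ["gx", "gy"]
        assert not rejected

    def test_u_mapped_to_t_and_upper(self):
        targets, _ = load_targets(io.StringIO(">A1\nacgu\n"))
        assert targets[0].sequence == "ACGT"

    def test_invalid_characters_rejected_with_report(self):
        targets, rejected = load_targets(io.StringIO(">A1\nACGT\n>A2\nACNGT\n"))
        assert [t.accession for t in targets] == ["A1"]
        assert rejected[0]["accession"] == "A2"
        assert "N" in rejected[0]["reason"]

    def test_empty_file_raises(self):
        with pytest.raises(ValueError, match="no FASTA"):
            load_targets(io.StringIO(""))

    def test_duplicate_accession_raises(self):
        with pytest.raises(ValueError, match="duplicate"):
            load_targets(io.StringIO(">A1\nACGT\n>A1\nACGT\n"))

    def test_panel_sized_fasta(self, tmp_path):
        path = tmp_path / "p.fa"
        write_fasta(synth_transcriptome(192, (300, 3000), 0.4, seed=7), path)
        targets, rejected = load_targets(path)
        assert len(targets) == 192 and not rejected


class TestWindows:
    def test_single_window_target(self):
        rng = np.random.default_rng(0)
        # craft until one passing 52-mer is found
        while True:
            t = TargetGene("T", "t", random_seq(rng, 52))
            windows = enumerate_windows(t, B1)
            if windows:
                break
        assert [w.start for w in windows] == [0]

    def test_two_windows_at_min_gap(self):
        # arithmetic oracle: next start >= previous + 52 + gap, so a fully
        # clean 106-nt target yields exactly starts [0, 54]
        rng = np.random.default_rng(1)
        for _ in range(500):
            t = TargetGene("T", "t", random_seq(rng, 106))
            windows = enumerate_windows(t, B1)
            if len(windows) == 2:
                assert [w.start for w in windows] == [0, 54]
                return
            assert len(windows) < 2 or windows[1].start >= 54
        pytest.fail("no clean 106-nt target found in 500 seeded draws")

    def test_polya_target_filtered_out(self):
        t = TargetGene("T", "t", "A" * 200)
        assert enumerate_windows(t, B1) == []

    def test_short_target_yields_nothing(self):
        t = TargetGene("T", "t", "ACGT" * 10)  # 40 nt < 52
        assert enumerate_windows(t, B1) == []


class TestAssembly:
    def _window(self, seed=5):
        rng = np.random.default_rng(seed)
        return ProbeWindow(0, random_seq(rng, 52))

    def test_oligo_lengths(self):
        pair = assemble_pair(self._window(), B1)
        assert len(pair.oligo_up) == len(pair.oligo_down) == 45

    def test_down_oligo_binding_region_is_revcomp_of_window_head(self):
        w = self._window()
        pair = assemble_pair(w, B1)
        assert pair.oligo_down[:25] == revcomp_oracle(w.sequence[:25])

    def test_up_oligo_binding_region_is_revcomp_of_window_tail(self):
        w = self._window()
        pair = assemble_pair(w, B1)
        assert pair.oligo_up[20:] == revcomp_oracle(w.sequence[27:])

    def test_halves_differ_on_random_windows(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            pair = assemble_pair(ProbeWindow(0, random_seq(rng, 52)), B1)
            assert pair.oligo_up != pair.oligo_down

    def test_malformed_amplifier_rejected(self):
        with pytest.raises(ValueError, match="18 nt"):
            Amplifier("BX", "ACGT", "ACGT")


class TestDesignProbeSet:
    def test_long_target_hits_pair_cap(self):
        rng = np.random.default_rng(21)
        t = TargetGene("T", "t", random_seq(rng, 2000))
        # brute-force: count all filter-passing greedy candidates without cap
        uncapped = enumerate_windows(t, B1, DesignParams(max_pairs=10**6))
        assert len(uncapped) > 15
        ps = design_probe_set(t, B1)
        assert ps.status == "ok" and len(ps.pairs) == 15

    def test_minimum_viable_set(self):
        rng = np.random.default_rng(3)
        while True:
            t = TargetGene("T", "t", random_seq(rng, 160))
            if len(enumerate_windows(t, B1)) == 3:
                break
        ps = design_probe_set(t, B1)
        assert ps.status == "ok" and len(ps.pairs) == 3

    def test_too_few_pairs_flagged(self):
        t = TargetGene("T", "t", "AC" * 30)  # room for exactly one window
        ps = design_probe_set(t, B1)
        assert ps.status == "too_few_pairs" and len(ps.pairs) == 1

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        t = TargetGene("T", "t", random_seq(rng, 800))
        assert design_probe_set(t, B1) == design_probe_set(t, B1)


@pytest.fixture(scope="module")
def designed():
    records = synth_transcriptome(100, (300, 3000), 0.4, seed=77)
    targets = [TargetGene(a, s, seq) for a, s, seq in records]
    return design_panel(targets)


class TestDesignerInvariants:
    """Exhaustive assertions over 100 seeded random targets."""

    def test_all_oligos_45nt_with_homopolymer_cap(self, designed):
        for ps in designed:
            for pair in ps.pairs:
                for oligo in (pair.oligo_up, pair.oligo_down):
                    assert len(oligo) == 45
                    assert max_homopolymer(oligo) <= 3

    def test_windows_sorted_and_non_overlapping(self, designed):
        for ps in designed:
            starts = [p.window.start for p in ps.pairs]
            assert starts == sorted(starts)
            for a, b in zip(ps.pairs, ps.pairs[1:]):
                assert b.window.start - a.window.end >= DEFAULT_PARAMS.min_gap

    def test_binding_regions_hit_target_revcomp_exactly(self, designed):
        """Independent string-search oracle: each 25-nt binding region occurs
        in revcomp(target) at the offset implied by its window."""
        for ps in designed:
            rc_target = revcomp_oracle(ps.target.sequence)
            n = len(ps.target)
            for pair in ps.pairs:
                w = pair.window
                up_bind = pair.oligo_up[20:]
                down_bind = pair.oligo_down[:25]
                assert rc_target.find(up_bind) != -1
                assert rc_target.find(down_bind) != -1
                # exact offsets: window tail maps to rc position n - end
                assert rc_target[n - w.end : n - w.end + 25] == up_bind
                assert rc_target[n - w.start - 25 : n - w.start] == down_bind

    def test_set_sizes_within_bounds(self, designed):
        for ps in designed:
            if ps.status == "ok":
                assert 3 <= len(ps.pairs) <= 15
            else:
                assert len(ps.pairs) < 3
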