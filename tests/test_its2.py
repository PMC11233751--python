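"""Anchored window extraction and exact-sequence tallying."""
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from amphihap import _dna
from amphihap.errors import AmbiguityError, SpecError
from amphihap.io import ReadBatch, SequenceRecord
from amphihap.its2 import (
    OTHER,
    HaplotypeCatalog,
    ITS2Window,
    assign_names,
    composition_report,
    extract_spanning,
    locate_window,
    tally,
)
from amphihap.simulate import make_haplotypes, make_nrdna_reference, simulate_reads


def brute_force_tally(sequences, window, max_anchor_mismatch=1):
    """Independent oracle: test every offset of every read (and its reverse
    complement) for left-anchor + window-length gap + right-anchor."""
    a = len(window.left_anchor)
    wl = window.end - window.start
    counts = Counter()
    for seq in sequences:
        found = None
        for oriented in (seq, _dna.revcomp(seq)):
            for i in range(len(oriented) - (wl + 2 * a) + 1):
                left = oriented[i : i + a]
                right = oriented[i + a + wl : i + 2 * a + wl]
                mm_l = sum(x != y for x, y in zip(left, window.left_anchor))
                mm_r = sum(x != y for x, y in zip(right, window.right_anchor))
                if mm_l <= max_anchor_mismatch and mm_r <= max_anchor_mismatch:
                    found = oriented[i + a : i + a + wl]
                    break
            if found is not None:
                break
        if found is not None and "N" not in found:
            counts[found] += 1
    return counts


@pytest.fixture
def toy_window():
    # left anchor AGTC | window ACGTACGTAT | right anchor CTGA
    # (anchors chosen not to be mutual reverse complements)
    reference = SequenceRecord(id="ref", residues="AAAAAGTCACGTACGTATCTGATTTT")
    return reference, locate_window(reference, 8, 10, anchor_len=4)


class TestLocateWindow:
    def test_anchors_copied_from_context(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 4000))
        reference = SequenceRecord(id="r", residues=seq)
        window = locate_window(reference, 2000, 133, anchor_len=8)
        assert window.left_anchor == seq[1992:2000]
        assert window.right_anchor == seq[2133:2141]
        assert (window.start, window.end) == (2000, 2133)

    def test_duplicate_anchor_is_ambiguous(self):
        core = "ACGTTGCA"
        seq = core + "ACGTACGTAT" + "GGCCTTAA" + "TT" + core + "AA"
        reference = SequenceRecord(id="r", residues=seq)
        with pytest.raises(AmbiguityError):
            locate_window(reference, 8, 10, anchor_len=8)

    def test_window_outside_reference(self):
        reference = SequenceRecord(id="r", residues="ACGTACGTACGT")
        with pytest.raises(SpecError):
            locate_window(reference, 2, 10, anchor_len=4)

    def test_reproduces_generator_window(self, small_spec):
        reference, window = make_nrdna_reference(small_spec)
        again = locate_window(
            reference, window.start, window.end - window.start,
            anchor_len=len(window.left_anchor),
        )
        assert again == window


class TestExtractSpanning:
    def test_constructed_hit_and_strand_symmetry(self, toy_window):
        reference, window = toy_window
        read = "TT" + reference.residues[4:22] + "GGAC"
        segment = extract_spanning(read, window)
        assert segment == "ACGTACGTAT"
        assert extract_spanning(_dna.revcomp(read), window) == segment

    def test_anchor_mismatch_tolerance(self, toy_window):
        _, window = toy_window
        read = "TT" + "AGTA" + "ACGTACGTAT" + "CTGA" + "GGAC"  # 1 mm in left anchor
        assert extract_spanning(read, window, max_anchor_mismatch=1) == "ACGTACGTAT"
        assert extract_spanning(read, window, max_anchor_mismatch=0) is None

    def test_n_in_segment_dropped(self, toy_window):
        _, window = toy_window
        read = "TT" + "AGTC" + "ACGTNCGTAT" + "CTGA" + "GGAC"
        assert extract_spanning(read, window) is None

    def test_length_variant_flag(self, toy_window):
        _, window = toy_window
        read = "TT" + "AGTC" + "ACGTAACGTAT" + "CTGA" + "GGA"  # 11 bp gap
        assert extract_spanning(read, window) is None
        assert (
            extract_spanning(read, window, keep_length_variants=True) == "ACGTAACGTAT"
        )

    def test_non_spanning_read(self, toy_window):
        _, window = toy_window
        assert extract_spanning("ACGTACGTACGTACGT", window) is None


class TestTally:
    def test_matches_brute_force_on_simulated_reads(self, small_spec):
        """Vectorised tally equals the exhaustive anchored scan, with errors on."""
        spec = replace(
            small_spec, n_spanning_reads_target=150, per_base_error=0.01, seed=11
        )
        reference, window = make_nrdna_reference(spec)
        catalog = make_haplotypes(
            reference.residues[window.start : window.end], 3, 2, spec.seed
        )
        r1, r2, _ = simulate_reads(reference, window, catalog, spec)
        sequences = [_dna.decode(s) for s in r1.seqs] + [
            _dna.decode(s) for s in r2.seqs
        ]
        oracle = brute_force_tally(sequences, window)
        result = tally((r1, r2), window, min_count=1, min_freq=0.0)
        assert result.counts == dict(oracle)
        assert result.total_spanning == sum(oracle.values())

    def test_strand_invariance(self, small_spec):
        spec = replace(small_spec, n_spanning_reads_target=100)
        reference, window = make_nrdna_reference(spec)
        catalog = make_haplotypes(
            reference.residues[window.start : window.end], 3, 2, spec.seed
        )
        r1, r2, _ = simulate_reads(reference, window, catalog, spec)
        flipped = ReadBatch(seqs=np.ascontiguousarray(_dna.revcomp_arr(r1.seqs)))
        assert (
            tally(r1, window).counts == tally(flipped, window).counts
        )

    def test_zero_spanning_flags_no_coverage(self, toy_window):
        _, window = toy_window
        result = tally(["ACGTACGTACGTACGTACGT"], window)
        assert result.no_coverage and result.total_spanning == 0

    def test_noise_floor_pools_rare_variants(self, toy_window):
        _, window = toy_window
        hit = "TT" + "AGTC" + "ACGTACGTAT" + "CTGA"
        rare = "TT" + "AGTC" + "ACGAACGTAT" + "CTGA"
        result = tally([hit] * 50 + [rare], window, min_count=2, min_freq=0.005)
        assert result.counts == {"ACGTACGTAT": 50, OTHER: 1}
        assert result.total_spanning == 51

    def test_seeded_subsampling_caps_depth(self, toy_window):
        _, window = toy_window
        hit_a = "TT" + "AGTC" + "ACGTACGTAT" + "CTGA"
        hit_b = "TT" + "AGTC" + "ACGAACGTAT" + "CTGA"
        reads = [hit_a] * 400 + [hit_b] * 200
        kwargs = dict(min_count=1, min_freq=0.0, max_spanning=100, subsample_seed=3)
        result = tally(reads, window, **kwargs)
        assert result.total_spanning == 100
        assert sum(result.counts.values()) == 100
        assert result.counts == tally(reads, window, **kwargs).counts

    def test_raising_min_count_never_adds_variants(self, toy_window, rng):
        _, window = toy_window
        variants = ["ACGTACGTAT", "ACGAACGTAT", "ACGAACGAAT", "TCGTACGTAT"]
        reads = [
            "TT" + "AGTC" + rng.choice(variants) + "CTGA" for _ in range(300)
        ]
        previous = None
        for min_count in (1, 2, 5, 20, 100):
            result = tally(reads, window, min_count=min_count, min_freq=0.0)
            n_variants = len([k for k in result.counts if k != OTHER])
            if previous is not None:
                assert n_variants <= previous
            previous = n_variants


class TestAssignNames:
    catalog = HaplotypeCatalog({"Type1": "ACGTACGTAT", "Type2a": "ACGAACGTAT"})

    def _result(self, counts):
        from amphihap.its2 import TallyResult

        return TallyResult(
            counts=counts,
            total_spanning=sum(counts.values()),
            n_reads=sum(counts.values()),
            n_skipped=0,
            min_count=2,
            min_freq=0.005,
        )

    def test_exact_match_and_novel_ordering(self):
        profile = assign_names(
            self._result(
                {"ACGAACGTAT": 60, "TTTTTTTTTT": 25, "GGGGGGGGGG": 25, OTHER: 2}
            ),
            self.catalog,
            sample_id="s1",
        )
        # novels in descending count order, lexicographic tie-break
        assert profile.counts == {
            "Type2a": 60, "Novel1": 25, "Novel2": 25, OTHER: 2
        }
        assert profile.variant_sequences["Novel1"] == "GGGGGGGGGG"

    def test_one_mismatch_is_novel_at_exact_matching(self):
        profile = assign_names(self._result({"ACGAACGTAA": 10}), self.catalog)
        assert profile.counts == {"Novel1": 10}

    def test_ambiguous_match_raises(self):
        with pytest.raises(AmbiguityError):
            assign_names(
                self._result({"ACGCACGTAT": 10}), self.catalog, max_mismatch=1
            )

    def test_conservation_of_counts(self, small_spec):
        spec = replace(small_spec, per_base_error=0.01, n_spanning_reads_target=300)
        reference, window = make_nrdna_reference(spec)
        catalog = make_haplotypes(
            reference.residues[window.start : window.end], 3, 2, spec.seed
        )
        r1, r2, _ = simulate_reads(reference, window, catalog, spec)
        result = tally((r1, r2), window)
        profile = assign_names(result, catalog)
        assert sum(profile.counts.values()) == profile.total_spanning
        freqs = profile.frequencies
        assert abs(sum(freqs.values()) - 1.0) < 1e-9


class TestCompositionReport:
    def test_rows_and_percentages(self, tmp_path):
        from amphihap.its2 import HaplotypeProfile

        profile = HaplotypeProfile(
            sample_id="s1",
            counts={"Type1": 600, "US1": 400},
            total_spanning=1000,
            catalog_names=("Type1", "US1"),
        )
        df = composition_report([profile], tmp_path, write_pies=False)
        by_hap = df.set_index("haplotype")
        assert by_hap.loc["Type1", "percent"] == 60
        assert by_hap.loc["US1", "percent"] == 40

    def test_no_coverage_row_and_file_count(self, tmp_path):
        from amphihap.its2 import HaplotypeProfile

        profiles = [
            HaplotypeProfile(sample_id=f"s{i}", counts={"Type1": 5}, total_spanning=5)
            for i in range(3)
        ] + [HaplotypeProfile(sample_id="empty", counts={}, total_spanning=0)]
        df = composition_report(profiles, tmp_path, write_pies=True)
        assert (df[df["sample"] == "empty"]["haplotype"] == "no coverage").all()
        assert len(list(tmp_path.glob("pie_*.png"))) == 4
        assert (tmp_path / "its2_composition.tsv").exists()
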