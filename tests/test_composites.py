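"""Dimer, overlap and cluster detection, and architecture serialization."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import occ
from helpers_oracle import brute_dimers, exhaustive_clusters
from motifarch import (
    DimerOccurrence,
    DimerPattern,
    architecture_of,
    architecture_string,
    call_clusters,
    compile_motif,
    detect_overlaps,
    find_dimers,
    parse_architecture,
    scan_cores,
)

PDM3 = DimerPattern("Pdm3_HoxPou", "PdmHox", "Pou", gap_min=2, gap_max=3)


def make_dimer(start, end, seq_id="s1", name="d"):
    """A dimer occupying [start, end) built from two abutting 5-mer motifs."""
    assert end - start >= 10
    first = occ("Hox", start, start + 5, seq_id=seq_id)
    second = occ("Cut", end - 5, end, seq_id=seq_id)
    return DimerOccurrence(name, first, second, second.start - first.end)


class TestFindDimers:
    def test_pdm3_worked_example(self):
        motifs = [compile_motif("PdmHox", "Pdm3", "TAAT"),
                  compile_motif("Pou", "Pdm3", "TGCAW")]
        occurrences = scan_cores("s1", "TAATGGTGCAA", motifs)
        dimers = find_dimers(occurrences, PDM3)
        assert len(dimers) == 1
        d = dimers[0]
        assert (d.first.start, d.first.end) == (0, 4)
        assert (d.second.start, d.second.end) == (6, 11)
        assert d.gap == 2

    def test_gap_outside_window_rejected(self):
        occurrences = [occ("PdmHox", 0, 4), occ("Pou", 6, 11)]
        wide = DimerPattern("p", "PdmHox", "Pou", gap_min=4, gap_max=6)
        assert find_dimers(occurrences, wide) == []

    def test_empty_occurrence_list(self):
        assert find_dimers([], PDM3) == []

    def test_missing_partner_warns_and_returns_empty(self):
        occurrences = [occ("PdmHox", 0, 4)]
        with pytest.warns(UserWarning, match="Pou"):
            assert find_dimers(occurrences, PDM3) == []

    def test_same_strand_policy_filters_antiparallel_pairs(self):
        occurrences = [occ("PdmHox", 0, 4, "+"), occ("Pou", 6, 11, "-")]
        strict = DimerPattern("p", "PdmHox", "Pou", 2, 3, "same_strand")
        assert find_dimers(occurrences, strict) == []
        assert len(find_dimers(occurrences, PDM3)) == 1  # policy "any"

    def test_occurrences_may_be_shared_between_dimers(self):
        occurrences = [occ("PdmHox", 0, 4), occ("PdmHox", 3, 7), occ("Pou", 6, 11)]
        pat = DimerPattern("p", "PdmHox", "Pou", gap_min=-5, gap_max=3)
        dimers = find_dimers(occurrences, pat)
        assert len(dimers) == 2  # both Hox occurrences pair the single Pou
        assert sorted(d.gap for d in dimers) == [-1, 2]

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_pair_enumeration(self, data):
        n = data.draw(st.integers(0, 40))
        occurrences = []
        for i in range(n):
            start = data.draw(st.integers(0, 120))
            k = data.draw(st.integers(3, 6))
            name = data.draw(st.sampled_from(["Hox", "Pou", "Cut"]))
            strand = data.draw(st.sampled_from("+-"))
            occurrences.append(occ(name, start, start + k, strand))
        pattern = DimerPattern(
            "p",
            data.draw(st.sampled_from(["Hox", "Pou"])),
            data.draw(st.sampled_from(["Pou", "Cut"])),
            gap_min=data.draw(st.integers(-4, 3)),
            gap_max=data.draw(st.integers(3, 10)),
            orientation_policy=data.draw(st.sampled_from(["any", "same_strand"])),
        )
        got = sorted(
            (d.first.start, d.first.end, d.first.strand,
             d.second.start, d.second.end, d.second.strand, d.gap)
            for d in find_dimers(occurrences, pattern)
        )
        assert got == brute_dimers(occurrences, pattern)


class TestDetectOverlaps:
    def test_partial_overlap_reported_once(self):
        pairs = detect_overlaps([occ("Pou", 10, 15), occ("Ebox", 13, 19)])
        assert len(pairs) == 1
        assert pairs[0].overlap_len == 2
        assert pairs[0].a.motif_name == "Pou"  # a < b by (start, motif_name)

    def test_half_open_adjacency_is_not_overlap(self):
        assert detect_overlaps([occ("Pou", 10, 15), occ("Ebox", 15, 21)]) == []

    def test_identical_intervals_full_overlap(self):
        pairs = detect_overlaps([occ("Pou", 10, 15), occ("Ebox", 10, 15)])
        assert len(pairs) == 1 and pairs[0].overlap_len == 5

    def test_same_motif_overlaps_ignored(self):
        assert detect_overlaps([occ("Pou", 10, 15), occ("Pou", 12, 17)]) == []

    def test_empty_in_empty_out(self):
        assert detect_overlaps([]) == []


class TestCallClusters:
    def test_or85a_style_three_dimer_cluster(self):
        # three dimers spanning [0, 20), [50, 70), [97, 117) condense into
        # one 117-bp cluster under a 120-bp span limit
        dimers = [make_dimer(0, 20), make_dimer(50, 70), make_dimer(97, 117)]
        calls = call_clusters(dimers, min_members=2, max_span=120)
        assert len(calls) == 1
        assert calls[0].n_members == 3
        assert calls[0].span == 117

    def test_single_dimer_cannot_form_a_cluster(self):
        assert call_clusters([make_dimer(0, 20)], min_members=2, max_span=120) == []

    def test_distant_dimers_do_not_cluster(self):
        dimers = [make_dimer(0, 20), make_dimer(500, 520)]
        assert call_clusters(dimers, min_members=2, max_span=150) == []

    @pytest.mark.parametrize("kwargs", [{"min_members": 1}, {"max_span": 0}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            call_clusters([make_dimer(0, 20)], **{"min_members": 2, "max_span": 100, **kwargs})

    def test_no_reported_cluster_is_a_subset_of_another(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(2, 12)
            dimers = [make_dimer(int(s), int(s) + 10 + int(rng.integers(0, 30)))
                      for s in rng.integers(0, 400, size=n)]
            calls = call_clusters(dimers, min_members=2, max_span=100)
            keys = [frozenset((d.start, d.end) for d in c.members) for c in calls]
            for i, a in enumerate(keys):
                for j, b in enumerate(keys):
                    assert i == j or not a < b

    def test_matches_exhaustive_subset_search(self):
        rng = np.random.default_rng(11)
        for trial in range(60):
            n = int(rng.integers(1, 13))
            dimers = [make_dimer(int(s), int(s) + 10 + int(rng.integers(0, 40)))
                      for s in rng.integers(0, 300, size=n)]
            min_members = int(rng.integers(2, 4))
            max_span = int(rng.integers(40, 200))
            got = {
                frozenset((d.start, d.end) for d in c.members)
                for c in call_clusters(dimers, min_members, max_span)
            }
            assert got == exhaustive_clusters(dimers, min_members, max_span)

    def test_matches_exhaustive_search_at_fifteen_dimers(self):
        rng = np.random.default_rng(3)
        dimers = [make_dimer(int(s), int(s) + 12 + int(rng.integers(0, 30)))
                  for s in rng.integers(0, 250, size=15)]
        got = {
            frozenset((d.start, d.end) for d in c.members)
            for c in call_clusters(dimers, 2, 120)
        }
        assert got == exhaustive_clusters(dimers, 2, 120)


class TestArchitectureStrings:
    def test_gap_serialization(self):
        s = architecture_string([occ("Hox", 0, 5), occ("Pou", 7, 12)])
        assert s == "Hox+.2.Pou+"

    def test_overlap_serialization(self):
        a, b = occ("Pou", 7, 12), occ("Ebox", 10, 16)
        pairs = detect_overlaps([a, b])
        assert architecture_string([a, b], pairs) == "Pou+~Ebox+"

    def test_empty_elements_serialize_to_empty_string(self):
        assert architecture_string([]) == ""

    def test_unlisted_overlap_element_rejected(self):
        a, b = occ("Pou", 7, 12), occ("Ebox", 10, 16)
        (pair,) = detect_overlaps([a, b])
        with pytest.raises(ValueError, match="not in the element list"):
            architecture_string([a], [pair])

    def test_minus_strand_and_negative_gap(self):
        s = architecture_string([occ("Hox", 0, 5, "-"), occ("Pou", 3, 8)])
        assert s == "Hox-.-2.Pou+"
        assert parse_architecture(s).links == (-2,)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.data())
    def test_round_trip(self, data):
        n = data.draw(st.integers(0, 8))
        elements, cursor = [], 0
        for i in range(n):
            cursor += data.draw(st.integers(-3, 15)) if elements else 0
            cursor = max(cursor, (elements[-1].start + 1) if elements else 0)
            k = data.draw(st.integers(3, 6))
            name = data.draw(st.sampled_from(["Hox", "Pou", "Ebox", "Cut"]))
            strand = data.draw(st.sampled_from("+-"))
            elements.append(occ(name, cursor, cursor + k, strand))
            cursor = elements[-1].end
        overlaps = detect_overlaps(elements)
        flagged = data.draw(st.sets(st.integers(0, max(0, len(overlaps) - 1))))
        chosen = [overlaps[i] for i in sorted(flagged)] if overlaps else []
        arch = architecture_of(elements, chosen)
        assert parse_architecture(architecture_string(elements, chosen)) == arch

    def test_moving_an_element_changes_the_string(self):
        """A 1-bp displacement (half a DNA turn, a full turn, 125 bp...)
        always yields a distinct architecture for gap-joined elements."""
        base = [occ("Hox", 0, 5), occ("Pou", 7, 12), occ("Ebox", 20, 26)]
        reference = architecture_string(base)
        for shift in (1, 5, 10, 125):
            moved = base[:2] + [occ("Ebox", 20 + shift, 26 + shift)]
            assert architecture_string(moved) != reference

    def test_toggling_an_overlap_changes_the_string(self):
        a, b = occ("Pou", 7, 12), occ("Ebox", 10, 16)
        pairs = detect_overlaps([a, b])
        assert architecture_string([a, b], pairs) != architecture_string([a, b], [])
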