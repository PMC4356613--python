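"""Synthetic promoter backgrounds, planted elements and cohorts."""
import math

import numpy as np
import pytest

from motifarch import (
    BackgroundModel,
    CohortSpec,
    OverlapConflictError,
    compile_motif,
    dimer_template,
    expected_motif_count,
    generate_background,
    generate_cohort,
    onecut_pair_template,
    or59b_cluster_template,
    overlap_template,
    pdm3_dimer_template,
    plant_architecture,
    pou_ebox_overlap_template,
    scan_cores,
)
from motifarch.simulate import at_rich_model


class TestBackground:
    def test_fixed_seed_is_reproducible(self):
        model = BackgroundModel(length=500, seed=42)
        assert generate_background(model) == generate_background(model)

    def test_different_seeds_differ(self):
        a = generate_background(BackgroundModel(length=500, seed=1))
        b = generate_background(BackgroundModel(length=500, seed=2))
        assert a != b

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            generate_background(BackgroundModel(length=0))

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError):
            BackgroundModel(base_probs=(0.5, 0.5, 0.5, 0.5))

    def test_at_rich_preset_is_at_rich(self):
        seq = generate_background(at_rich_model(length=20000, seed=3))
        at = (seq.count("A") + seq.count("T")) / len(seq)
        assert 0.57 < at < 0.63

    def test_mean_kmer_count_matches_window_expectation(self):
        """Over 1000 uniform 1 kb sequences the mean both-strand count of a
        fully specified 5-mer sits within 3 SE of 2 * 996 * 4^-5."""
        motif = compile_motif("Hox", "Acj6", "AATTA")
        model = BackgroundModel(length=1000)
        rng = np.random.default_rng(12345)
        counts = np.array(
            [
                len(scan_cores("s", generate_background(model, rng=rng), [motif]))
                for _ in range(1000)
            ]
        )
        expected = expected_motif_count("AATTA", 1000)
        assert expected == pytest.approx(2 * 996 * 4**-5)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se


class TestPlantArchitecture:
    def test_fixed_gap_dimer_truth_coordinates(self):
        template = dimer_template(
            "Pdm3", ("PdmHox", "TAAT"), ("Pou", "TGCAW"), gap=2
        )
        background = generate_background(BackgroundModel(seed=7))
        seq, element = plant_architecture(background, template, position=100, seed=1)
        assert len(seq) == len(background)  # overwrite, never insert
        (hox, pou) = element.truth
        assert (hox.start, hox.end) == (100, 104)
        assert (pou.start, pou.end) == (106, 111)
        assert seq[100:104] == "TAAT"
        assert seq[104:106] == background[104:106]  # gap bases untouched

    def test_incompatible_overlap_rejected_with_positions(self):
        # sharing 2 bp forces A over C at one position: unsatisfiable
        template = overlap_template(
            "bad", ("Pou", "TGCAW"), ("Ebox", "CANNTG"), shift=3
        )
        background = generate_background(BackgroundModel(seed=7))
        with pytest.raises(OverlapConflictError) as exc:
            plant_architecture(background, template, position=10, seed=0)
        assert exc.value.positions == (3,)

    def test_compatible_overlap_satisfies_both_patterns(self):
        template = pou_ebox_overlap_template()
        background = generate_background(BackgroundModel(seed=7))
        seq, element = plant_architecture(background, template, position=50, seed=0)
        pou_m = compile_motif("Pou", "Acj6", "TGCAW")
        ebox = compile_motif("Ebox", "Fer1", "CANNTG")
        starts = {
            (o.motif_name, o.start)
            for o in scan_cores("s", seq, [pou_m, ebox], strands=("+",))
        }
        assert {("Pou", 50), ("Ebox", 52)} <= starts

    @pytest.mark.parametrize(
        "template_factory",
        [pdm3_dimer_template, pou_ebox_overlap_template,
         onecut_pair_template, or59b_cluster_template],
    )
    def test_every_planted_motif_is_recovered_by_the_scanner(self, template_factory):
        """Soundness by construction: zero false negatives at zero mutation."""
        template = template_factory()
        motifs = [
            compile_motif("Hox", "Acj6", "AATTA"),
            compile_motif("Pou", "Acj6", "TGCAW"),
            compile_motif("PdmHox", "Pdm3", "TAAT"),
            compile_motif("Ebox", "Fer1", "CANNTG"),
            compile_motif("Cut", "Onecut", "ATCAA"),
        ]
        rng = np.random.default_rng(99)
        for _ in range(20):
            background = generate_background(BackgroundModel(), rng=rng)
            seq, element = plant_architecture(background, template, rng=rng)
            found = {
                (o.motif_name, o.start, o.end, o.strand)
                for o in scan_cores("s", seq, motifs)
            }
            for t in element.truth:
                assert (t.motif_name, t.start, t.end, t.strand) in found

    def test_template_must_fit_at_position(self):
        template = pdm3_dimer_template()
        with pytest.raises(ValueError, match="fit"):
            plant_architecture("ACGT" * 5, template, position=15, seed=0)


class TestGenerateCohort:
    def test_extreme_probabilities_plant_deterministically(self):
        spec = CohortSpec(
            n_reg=5, n_non=5, p_reg=1.0, p_non=0.0,
            element=pdm3_dimer_template(),
            background=BackgroundModel(length=200),
            seed=11,
        )
        cohort = generate_cohort(spec)
        planted = cohort.truth.set_index("seq_id")["planted"]
        assert all(planted[f"reg_{i:03d}"] for i in range(1, 6))
        assert not any(planted[f"non_{i:03d}"] for i in range(1, 6))
        assert set(cohort.planted) == {f"reg_{i:03d}" for i in range(1, 6)}

    def test_identical_spec_and_seed_reproduce_byte_identical_output(self):
        spec = CohortSpec(
            n_reg=4, n_non=4, p_reg=0.5, p_non=0.5,
            element=onecut_pair_template(), seed=21,
        )
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert a.records == b.records
        assert a.truth.equals(b.truth)
        assert a.labels.equals(b.labels)

    def test_oversized_element_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_cohort(
                CohortSpec(
                    n_reg=1, n_non=1, p_reg=1.0, p_non=0.0,
                    element=onecut_pair_template(),
                    background=BackgroundModel(length=30),
                )
            )

    def test_labels_match_groups(self):
        spec = CohortSpec(
            n_reg=3, n_non=2, p_reg=0.5, p_non=0.5,
            element=pdm3_dimer_template(), background=BackgroundModel(length=100),
        )
        cohort = generate_cohort(spec)
        assert cohort.regulated_ids == {"reg_001", "reg_002", "reg_003"}
        assert len(cohort.records) == 5
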