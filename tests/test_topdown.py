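"""Fragment generation/matching, parent reconstruction, label localization."""

import random

import numpy as np
import pytest

from metalloform import (
    FragmentAnnotation,
    MetalloformComposition,
    Spectrum,
    complementary_reconstruction,
    fragmentation_map,
    generate_fragments,
    localize_labels,
    match_fragments,
    neutral_mass,
    simulate_fragments,
)


@pytest.fixture(scope="module")
def cu4nem10(protein):
    return MetalloformComposition(n_cu=4, n_nem=10, z=5)


@pytest.fixture(scope="module")
def fragments(protein, cu4nem10):
    return generate_fragments(protein, cu4nem10)


def _annotation(candidate):
    return FragmentAnnotation(candidate, candidate.mz, 0.0, 1.0)


def _find(cands, ion_type, index, **adducts):
    for c in cands:
        if c.ion_type != ion_type or c.index != index:
            continue
        if all(c.adducts.get(k, 0) == v for k, v in adducts.items()):
            extra = sum(v for k, v in c.adducts.items() if k not in adducts)
            if extra == 0:
                return c
    raise AssertionError(f"{ion_type}{index} with {adducts} not generated")


class TestGeneration:
    def test_complementary_pairs_conserve_mass_and_adducts(self, protein, cu4nem10):
        """Every b_i/y_{n-i} partition pair sums exactly to the parent."""
        parent_mass = neutral_mass(protein, cu4nem10, "monoisotopic")
        cands = generate_fragments(protein, cu4nem10, charges=(1,))
        by_key = {}
        for c in cands:
            by_key.setdefault((c.ion_type, c.index), []).append(c)
        n = protein.n_residues
        parent_counts = cu4nem10.adduct_counts()
        checked = 0
        for i in (1, 6, 20, 34, 62, 67):
            for b in by_key.get(("b", i), []):
                target = {
                    k: parent_counts.get(k, 0) - b.adducts.get(k, 0)
                    for k in b.adducts
                }
                complements = [
                    y
                    for y in by_key.get(("y", n - i), [])
                    if all(y.adducts.get(k, 0) == v for k, v in target.items())
                ]
                for y in complements:
                    assert b.neutral_mass + y.neutral_mass == pytest.approx(
                        parent_mass, abs=1e-6
                    )
                    checked += 1
        assert checked > 0

    def test_ss_partition_mode_conserves_full_parent_mass(self, protein):
        parent = MetalloformComposition(n_nem=2, n_ss=2, z=5)
        parent_mass = neutral_mass(protein, parent, "monoisotopic")
        cands = generate_fragments(protein, parent, charges=(1,), ss_mode="partition")
        b = next(
            c for c in cands
            if c.ion_type == "b" and c.index == 34 and c.adducts["SS"] == 1
            and c.adducts["NEM"] == 1
        )
        y = next(
            c for c in cands
            if c.ion_type == "y" and c.index == 34 and c.adducts["SS"] == 1
            and c.adducts["NEM"] == 1
        )
        assert b.neutral_mass + y.neutral_mass == pytest.approx(parent_mass, abs=1e-6)

    def test_parent_only_mode_keeps_ss_off_fragments(self, protein):
        parent = MetalloformComposition(n_ss=2, z=5)
        cands = generate_fragments(protein, parent, charges=(1,))
        assert all(c.adducts["SS"] == 0 for c in cands)

    def test_label_partition_capped_by_span_cysteines(self, protein, fragments):
        for c in fragments:
            span = c.span(protein.n_residues)
            assert c.adducts["NEM"] <= protein.cys_in_span(*span)

    def test_b6_one_nem_and_y62_nine_nem_exist(self, protein, fragments):
        # residues 1..6 contain exactly one Cys (position 6)
        assert protein.cys_in_span(1, 6) == 1
        _find(fragments, "b", 6, NEM=1)
        _find(fragments, "y", 62, NEM=9)

    def test_overbudget_parent_rejected(self, protein):
        parent = MetalloformComposition(n_nem=19, n_ss=2, z=5)
        with pytest.raises(ValueError, match="Cys"):
            generate_fragments(protein, parent)


class TestMatching:
    def test_planted_fragments_recovered(self, protein, cu4nem10, fragments):
        cys = protein.cys_positions()
        placement = {6: "NEM", 8: "NEM", **{p: "NEM" for p in cys[-8:]}}
        spectrum, planted = simulate_fragments(
            protein, cu4nem10, placement, indices=range(1, 68), seed=3
        )
        annotations = match_fragments(spectrum, fragments, 20.0)
        # every planted peak annotated, none invented
        assert len(annotations) == len(planted)
        planted_mz = np.sort([c.mz for c in planted])
        identity_ok = 0
        for ann in annotations:
            j = np.argmin(np.abs(planted_mz - ann.obs_mz))
            assert abs(planted_mz[j] - ann.obs_mz) / ann.obs_mz < 2e-6
            truth = sorted(planted, key=lambda c: c.mz)[j]
            if (ann.candidate.ion_type, ann.candidate.index) == (
                truth.ion_type,
                truth.index,
            ):
                identity_ok += 1
        assert identity_ok / len(annotations) >= 0.95

    def test_empty_spectrum_empty_result(self, fragments):
        empty = Spectrum(np.array([]), np.array([]), "centroid")
        assert match_fragments(empty, fragments) == []

    def test_tolerance_threshold_semantics(self, protein):
        parent = MetalloformComposition(z=1)
        cands = [
            c for c in generate_fragments(protein, parent, types=("b",), charges=(1,))
            if c.index == 10
        ]
        base = cands[0].mz
        # peak 25 ppm above the candidate: matched at 30 ppm, not at 20 ppm
        peak = Spectrum(np.array([base * (1 + 25e-6)]), np.array([1.0]), "centroid")
        assert len(match_fragments(peak, cands, 30.0)) == 1
        assert match_fragments(peak, cands, 20.0) == []

    def test_ppm_within_tolerance(self, protein, fragments):
        cys = protein.cys_positions()
        placement = {6: "NEM", 8: "NEM", **{p: "NEM" for p in cys[-8:]}}
        spectrum, _ = simulate_fragments(
            protein,
            MetalloformComposition(n_cu=4, n_nem=10, z=5),
            placement,
            indices=range(1, 68),
            seed=9,
        )
        for ann in match_fragments(spectrum, fragments, 20.0):
            assert abs(ann.ppm) <= 20.0


class TestReconstruction:
    def test_b6_y62_reconstructs_parent(self, protein, fragments):
        b6 = _find(fragments, "b", 6, NEM=1)
        y62 = _find(fragments, "y", 62, NEM=9, Cu_I=4)
        parent = complementary_reconstruction(_annotation(b6), _annotation(y62), protein)
        assert parent.n_nem == 10
        assert parent.n_cu == 4
        assert b6.index + y62.index == protein.n_residues == 68

    def test_b1_plus_full_y_equals_y_partition(self, protein, fragments):
        b1 = _find(fragments, "b", 1)
        y67 = _find(fragments, "y", 67, NEM=10, Cu_I=4)
        parent = complementary_reconstruction(_annotation(b1), _annotation(y67), protein)
        assert (parent.n_cu, parent.n_nem) == (4, 10)

    def test_non_complementary_pair_fails(self, protein, fragments):
        b6 = _find(fragments, "b", 6, NEM=1)
        y61 = _find(fragments, "y", 61, NEM=9)
        with pytest.raises(ValueError, match="not complementary"):
            complementary_reconstruction(_annotation(b6), _annotation(y61), protein)


class TestLocalization:
    def _printed_ladder(self, protein):
        """The b2-b8 ladder reported for the 4-Cu, 10-NEM precursor."""
        parent = MetalloformComposition(n_cu=4, n_nem=10, z=5)
        cands = generate_fragments(protein, parent, types=("b",), charges=(1,))
        ladder = {2: 0, 3: 0, 4: 0, 5: 0, 6: 1, 7: 1, 8: 2}
        return [
            _annotation(_find(cands, "b", idx, NEM=nem)) for idx, nem in ladder.items()
        ]

    def test_printed_ladder_localizes_cys6_and_cys8(self, protein):
        result = localize_labels(self._printed_ladder(protein), protein)
        assert result.positions("labeled-NEM") == [6, 8]
        assert result.conflicts == []

    def test_localization_order_invariant(self, protein):
        anns = self._printed_ladder(protein)
        shuffled = anns.copy()
        random.Random(0).shuffle(shuffled)
        a = localize_labels(anns, protein)
        b = localize_labels(shuffled, protein)
        assert a.states == b.states

    def test_all_zero_ladder_marks_covered_cys_unmodified(self, protein):
        parent = MetalloformComposition(z=5)
        cands = generate_fragments(protein, parent, types=("b",), charges=(1,))
        anns = [_annotation(_find(cands, "b", i)) for i in range(2, 9)]
        result = localize_labels(anns, protein)
        assert set(result.states.values()) == {"unmodified"}

    def test_ambiguous_interval_undetermined(self, protein):
        # jump b5 -> b8 with +1 NEM brackets Cys6 and Cys8 at once
        parent = MetalloformComposition(n_nem=1, z=5)
        cands = generate_fragments(protein, parent, types=("b",), charges=(1,))
        anns = [
            _annotation(_find(cands, "b", 5)),
            _annotation(_find(cands, "b", 8, NEM=1)),
        ]
        result = localize_labels(anns, protein)
        assert result.states[6] == "undetermined"
        assert result.states[8] == "undetermined"

    def test_end_to_end_planted_placement_recovery(self, protein):
        cys = protein.cys_positions()
        placement = {6: "NEM", 8: "NEM", **{p: "NEM" for p in cys[-8:]}}
        parent = MetalloformComposition(n_cu=4, n_nem=10, z=5)
        spectrum, _ = simulate_fragments(
            protein, parent, placement, indices=range(1, 68), seed=3
        )
        cands = generate_fragments(protein, parent)
        result = localize_labels(match_fragments(spectrum, cands, 20.0), protein)
        assert set(result.positions("labeled-NEM")) == set(placement)
        unlabeled = set(cys) - set(placement)
        assert unlabeled <= set(
            result.positions("unmodified") + result.positions("undetermined")
        )


class TestFragmentationMap:
    def test_empty_annotations_zero_coverage(self, protein):
        table, coverage = fragmentation_map([], protein)
        assert coverage == 0.0
        assert len(table) == protein.n_residues - 1

    def test_full_b_ladder_full_coverage(self, protein):
        parent = MetalloformComposition(z=5)
        cands = generate_fragments(protein, parent, types=("b",), charges=(1,))
        anns = [_annotation(_find(cands, "b", i)) for i in range(1, 68)]
        table, coverage = fragmentation_map(anns, protein)
        assert coverage == 100.0
        assert (table["n_ions"] >= 1).all()

    def test_simulated_map_reproducible(self, protein):
        placement = {6: "NEM", 8: "NEM"}
        parent = MetalloformComposition(n_nem=2, z=5)
        spectrum, planted = simulate_fragments(
            protein, parent, placement, types=("b",), indices=range(1, 35), seed=8
        )
        cands = generate_fragments(protein, parent, types=("b",), charges=(1,))
        anns = match_fragments(spectrum, cands, 20.0)
        table, coverage = fragmentation_map(anns, protein)
        planted_sites = {
            c.index if c.ion_type == "b" else protein.n_residues - c.index
            for c in planted
        }
        covered_sites = set(table.loc[table["n_ions"] > 0, "site"])
        assert covered_sites == planted_sites
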