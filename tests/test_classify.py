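"""Haplogroup classification, APLP band calling and molecular sexing."""

import random

import pytest

from haplopipe import (
    SampleRecord,
    call_allele_from_bands,
    call_sex,
    classify_mtdna,
    classify_y,
    load_panel,
    motif,
    parse_motif,
)
from haplopipe.classify import (
    AssayError,
    ConsistencyError,
    DiagnosticMarker,
    MarkerPanel,
    PanelError,
)
from haplopipe.synth import marker_calls_for_label, observed_value_for


@pytest.fixture(scope="module")
def panel():
    return load_panel()


class TestBandCalling:
    def test_macrohaplogroup_m_band(self, panel):
        marker = panel.mtdna.markers["M"]
        assert call_allele_from_bands(marker, {149}).allele == "T"
        assert call_allele_from_bands(marker, {142}).allele == "C"

    def test_nine_bp_deletion_band(self, panel):
        marker = panel.mtdna.markers["B"]
        call = call_allele_from_bands(marker, {112})
        assert call.allele == "del9" and call.status == "ok"
        assert call_allele_from_bands(marker, {121}).allele == "nodel"

    def test_both_bands_is_a_mixture_signal(self, panel):
        call = call_allele_from_bands(panel.mtdna.markers["M"], {149, 142})
        assert call.status == "mixture" and call.allele is None

    def test_no_matching_band_is_no_call(self, panel):
        assert call_allele_from_bands(panel.mtdna.markers["M"], {500}).status == "no-call"

    def test_sequencing_marker_rejected(self, panel):
        with pytest.raises(AssayError):
            call_allele_from_bands(panel.mtdna.markers["R"], {151})

    def test_band_calling_inverts_the_band_generator(self, panel):
        """Every band-assay marker round-trips allele -> length -> allele."""
        for p in (panel.mtdna, panel.y):
            for marker in p.markers.values():
                if marker.assay not in ("APLP", "deletion-length"):
                    continue
                for allele in marker.band_lengths:
                    length = int(observed_value_for(marker, allele))
                    assert call_allele_from_bands(marker, {length}).allele == allele


class TestClassifyMtdna:
    def _sample(self, calls, haplotype):
        return SampleRecord("x", parse_motif(haplotype), coding_calls=calls)

    def test_c4_from_coding_cascade(self, panel):
        s = self._sample({"M": "T", "R": "T", "C": "C", "C4": "A"}, "298-327")
        call = classify_mtdna(s, panel.mtdna)
        assert call.label == "C4" and call.terminal
        assert s.mtdna_haplogroup == "C4"
        assert any("consistent with C4" in a for a in call.advisories)

    def test_m_star_when_lineage_c_excluded(self, panel):
        s = self._sample({"M": "T", "R": "T", "C": "T"}, "223-304")
        call = classify_mtdna(s, panel.mtdna)
        assert call.label == "M*" and not call.terminal

    def test_r_star_when_all_tested_subclades_ancestral(self, panel):
        calls = {"M": "C", "R": "C", "UK": "A", "HV": "C", "R1": "A",
                 "R11": "T", "F": "C", "B": "nodel"}
        s = self._sample(calls, "189-192-311")
        call = classify_mtdna(s, panel.mtdna)
        assert call.label == "R*" and not call.terminal

    def test_k_is_a_motif_refinement_of_uk(self, panel):
        calls = marker_calls_for_label(panel.mtdna, "K")
        s = self._sample(calls, "93-134-224-311-390")
        call = classify_mtdna(s, panel.mtdna)
        assert call.label == "K"
        assert any("refined" in a for a in call.advisories)
        # without the K-consistent motif the label stays at the tested marker
        s2 = self._sample(calls, "260")
        assert classify_mtdna(s2, panel.mtdna).label == "UK"

    def test_missing_branching_marker_reports_incomplete(self, panel):
        s = self._sample({"M": "T", "R": "T"}, "298-327")  # C untested
        call = classify_mtdna(s, panel.mtdna)
        assert call.status == "incomplete" and call.missing_marker == "C"
        assert s.mtdna_haplogroup == ""  # output only set on a clean call

    def test_cohort_haplogroup_column_reproduced_exactly(self, study):
        for sample, expected in zip(study.samples, study.expected.itertuples()):
            call = classify_mtdna(sample, study.panel.mtdna)
            assert call.status == "ok"
            assert call.label == expected.mtdna_hg, sample.sample_id
        from collections import Counter

        counts = Counter(s.mtdna_haplogroup for s in study.samples)
        assert counts == {"C4": 14, "R*": 3, "M*": 1, "K": 1, "H": 1}

    def test_call_path_is_a_root_to_node_walk(self, study):
        """Derived steps must follow parent links of the marker tree."""
        panel = study.panel.mtdna
        for sample in study.samples:
            call = classify_mtdna(sample, panel)
            derived = [st for st in call.path if st.derived]
            labels = [panel.root_label] + [st.implies for st in derived]
            for step, parent_label in zip(derived, labels):
                marker = panel.markers[step.marker]
                expect = None if parent_label == panel.root_label else parent_label
                assert marker.parent == expect


class TestClassifyY:
    def _male(self, y_calls):
        s = SampleRecord("m", motif([]), y_calls=y_calls)
        s.molecular_sex = "male"
        return s

    def test_full_cascade_reaches_r1a1a(self, panel):
        calls = {"M89": "T", "M9": "G", "M45": "A", "M173": "A", "M198": "A"}
        call = classify_y(self._male(calls), panel.y)
        assert call.label == "R1a1a" and call.terminal

    def test_cascade_stops_at_ancestral_root(self, panel):
        call = classify_y(self._male({"M89": "C"}), panel.y)
        assert call.label == "pre-F*"

    def test_intermediate_stop_gets_star(self, panel):
        calls = {"M89": "T", "M9": "G", "M45": "G"}
        call = classify_y(self._male(calls), panel.y)
        assert call.label == "K*"

    def test_female_sample_rejected(self, panel):
        s = SampleRecord("f", motif([]), y_calls={"M89": "T"})
        s.molecular_sex = "female"
        with pytest.raises(ConsistencyError):
            classify_y(s, panel.y)

    def test_order_independent_of_call_map(self, panel):
        items = [("M89", "T"), ("M9", "G"), ("M45", "A"), ("M173", "A"), ("M198", "A")]
        rng = random.Random(3)
        for _ in range(5):
            rng.shuffle(items)
            assert classify_y(self._male(dict(items)), panel.y).label == "R1a1a"

    def test_all_seven_cohort_males_are_r1a1a(self, study):
        from haplopipe.pipeline import profile_samples

        profile_samples(study.samples, study.panel)
        males = [s for s in study.samples if s.molecular_sex == "male"]
        assert len(males) == 7
        assert all(s.y_haplogroup == "R1a1a" for s in males)


class TestCallSex:
    def test_both_bands_male(self, panel):
        assert call_sex({115, 121}, panel.amg).sex == "male"

    def test_x_band_only_female(self, panel):
        assert call_sex({115}, panel.amg).sex == "female"

    def test_y_band_only_male_with_dropout_note(self, panel):
        call = call_sex({121}, panel.amg)
        assert call.sex == "male" and "dropout" in call.note

    def test_no_bands_no_call(self, panel):
        assert call_sex(set(), panel.amg).sex == "no-call"

    def test_unregistered_band_is_an_assay_error(self, panel):
        with pytest.raises(AssayError):
            call_sex({115, 300}, panel.amg)


class TestPanelStructure:
    def test_packaged_panel_loads_and_is_a_tree(self, panel):
        assert set(panel.mtdna.markers) == {
            "M", "R", "C", "C4", "UK", "HV", "H", "R1", "R11", "B", "F"
        }
        assert [m.name for m in panel.y.children_of("pre-F")] == ["M89"]

    def test_band_assay_requires_two_lengths(self):
        with pytest.raises(PanelError):
            DiagnosticMarker(name="x", defining_allele="T", implies="X",
                             parent=None, assay="APLP", band_lengths={"T": 100})

    def test_cycle_is_rejected(self):
        a = DiagnosticMarker(name="a", defining_allele="T", implies="A", parent="B")
        b = DiagnosticMarker(name="b", defining_allele="T", implies="B", parent="A")
        with pytest.raises(PanelError):
            MarkerPanel([a, b])
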