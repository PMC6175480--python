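import pytest

from uorfkit import (
    AnnotationConfig,
    Classification,
    apply_variants,
    classify_variant_set,
    parse_hgvs_c,
    predicted_extension_mass,
)
from uorfkit.consequence import _uorf_repression_flag
from uorfkit.orf import ORFRecord, OrfKind
from uorfkit.transcript import TranscriptModel


def _classify(model, *hgvs, config=None):
    return classify_variant_set(model, [parse_hgvs_c(h) for h in hgvs], config)


class TestClassifyConstructSeries:
    def test_dual_cis_pair_repressive_uorf(self, fixture_model):
        r = _classify(fixture_model, "c.-281G>T", "c.-263C>A")
        assert r.classification == Classification.UAUG_CREATED_UORF
        assert r.repression_flag == "predicted_repressive"
        assert r.orf.codons_incl_stop == 68

    def test_shortened_uorf_tolerated(self, fixture_model):
        r = _classify(fixture_model, "c.-263C>A", "c.-252T>A")
        assert r.classification == Classification.UAUG_CREATED_UORF
        assert r.orf.codons_incl_stop == 4
        assert r.orf.dist_stop_end_to_saug == 251
        assert r.repression_flag == "predicted_tolerated"

    def test_inert_variant(self, fixture_model):
        r = _classify(fixture_model, "c.-281G>T")
        assert r.classification == Classification.NO_UAUG_CHANGE
        assert r.orf is None
        assert r.repression_flag == "not_applicable"

    def test_inframe_extension(self, fixture_model):
        r = _classify(fixture_model, "c.-255G>A")
        assert r.classification == Classification.UAUG_CREATED_INFRAME_EXTENSION
        assert r.orf.extension_codons == 85
        assert r.extension_mass_kda == pytest.approx(9.35)
        assert r.repression_flag == "predicted_repressive"
        assert "unstable" in r.notes or "unresolved" in r.notes

    def test_short_uorf_far_from_saug_tolerated(self, fixture_model):
        r = _classify(fixture_model, "c.-255G>A", "c.-246C>T")
        assert r.orf.codons_excl_stop == 3
        assert r.repression_flag == "predicted_tolerated"

    def test_long_uorf_from_minus255_repressive(self, fixture_model):
        r = _classify(fixture_model, "c.-255G>A", "c.-75C>T")
        assert r.orf.codons_incl_stop == 61
        assert r.repression_flag == "predicted_repressive"


class TestOtherEventClasses:
    @pytest.fixture()
    def mutant_model(self, fixture_model):
        seq = apply_variants(fixture_model, [parse_hgvs_c("c.-263C>A")])
        return TranscriptModel(id="mut", sequence=seq, utr5_length=fixture_model.utr5_length)

    def test_uaug_destroyed(self, mutant_model):
        r = _classify(mutant_model, "c.-263A>C")
        assert r.classification == Classification.UAUG_DESTROYED
        assert "c.-263" in r.notes

    def test_uorf_stop_created(self, mutant_model):
        r = _classify(mutant_model, "c.-252T>A")
        assert r.classification == Classification.UORF_STOP_CREATED
        assert r.orf.codons_incl_stop == 4
        assert r.repression_flag == "predicted_tolerated"

    def test_uorf_stop_destroyed(self, fixture_model, mutant_model):
        # removing the natural stop turns the uORF into an overlapping ORF
        r = _classify(mutant_model, "c.-61G>C")
        assert r.classification == Classification.UORF_STOP_DESTROYED
        assert r.repression_flag == "predicted_repressive"


class TestExtensionMass:
    def test_family2_mass(self):
        raw, rounded = predicted_extension_mass(85)
        assert raw == pytest.approx(9.35)
        assert rounded == 9

    def test_linearity(self):
        raw, rounded = predicted_extension_mass(100)
        assert raw == pytest.approx(11.0)
        assert rounded == 11

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            predicted_extension_mass(0)


class TestHeuristic:
    @staticmethod
    def _flag(codons, dist, cfg=None):
        rec = ORFRecord(
            start=-(3 * codons + dist + 2),
            kind=OrfKind.UORF,
            frame_offset=0,
            stop_first=-(dist + 3),
            stop_last=-(dist + 1),
            length_nt=3 * codons,
            codons_incl_stop=codons,
            codons_excl_stop=codons - 1,
            dist_stop_end_to_saug=dist,
            dist_stop_start_to_saug=dist + 3,
        )
        return _uorf_repression_flag(rec, cfg or AnnotationConfig())

    @pytest.mark.parametrize(
        "codons,dist,flag",
        [
            (68, 59, "predicted_repressive"),
            (4, 251, "predicted_tolerated"),
            (4, 243, "predicted_tolerated"),
            (61, 72, "predicted_repressive"),
            (4, 150, "predicted_repressive"),  # short but too close
            (10, 400, "predicted_repressive"),  # long enough regardless
        ],
    )
    def test_threshold_rules(self, codons, dist, flag):
        assert self._flag(codons, dist) == flag

    def test_monotone_severity(self):
        """Moving a uORF stop 3 nt downstream (one codon longer, 3 nt closer)
        never flips predicted_repressive to predicted_tolerated."""
        for codons in range(1, 80):
            for dist in range(0, 320, 7):
                if self._flag(codons, dist) == "predicted_repressive":
                    assert (
                        self._flag(codons + 1, max(dist - 3, 0))
                        == "predicted_repressive"
                    )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnnotationConfig(min_repressive_uorf_codons=0)


class TestReportContract:
    def test_determinism(self, fixture_model):
        a = _classify(fixture_model, "c.-263C>A")
        b = _classify(fixture_model, "c.-263C>A")
        assert a == b and a.to_dict() == b.to_dict()

    def test_extension_implies_mass(self, fixture_model):
        r = _classify(fixture_model, "c.-255G>A")
        assert r.extension_mass_kda is not None

    def test_dict_column_contract(self, fixture_model):
        from uorfkit.consequence import REPORT_COLUMNS

        d = _classify(fixture_model, "c.-263C>A").to_dict()
        assert tuple(d) == REPORT_COLUMNS
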