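import pytest

from uorfkit import (
    OrfKind,
    apply_variants,
    delineate_orf,
    diff_uaug_events,
    find_augs,
    find_leader_augs,
    frame_offset,
    parse_hgvs_c,
    random_transcript,
)
from uorfkit.oracle import oracle_delineate
from uorfkit.transcript import TranscriptModel, c_to_index


def _mut(model, *hgvs):
    return apply_variants(model, [parse_hgvs_c(h) for h in hgvs])


class TestFindAugs:
    def test_overlapping_matches_all_reported(self):
        assert find_augs("ATGATG") == [0, 3]
        assert find_augs("ATATGG") == [2]

    def test_wt_leader_has_no_aug(self, fixture_model):
        assert find_leader_augs(fixture_model) == []

    def test_created_aug_found(self, fixture_model):
        alt = _mut(fixture_model, "c.-255G>A")
        assert find_leader_augs(fixture_model, alt) == [-255]

    def test_n_never_matches(self):
        assert find_augs("ANGATN") == []


class TestFrameOffset:
    @pytest.mark.parametrize("start,offset", [(-255, 0), (-3, 0), (-263, 2), (-62, 2), (-61, 1)])
    def test_values(self, start, offset):
        assert frame_offset(start) == offset
        assert (frame_offset(start) == 0) == (abs(start) % 3 == 0)

    def test_positive_rejected(self):
        with pytest.raises(ValueError):
            frame_offset(1)


class TestDelineateOrf:
    def test_family1_uorf(self, fixture_model):
        alt = _mut(fixture_model, "c.-263C>A")
        rec = delineate_orf(fixture_model, -263, sequence=alt)
        assert rec.kind is OrfKind.UORF
        assert (rec.stop_first, rec.stop_last) == (-62, -60)
        assert rec.length_nt == 204
        assert rec.codons_incl_stop == 68
        assert rec.codons_excl_stop == 67
        assert rec.dist_stop_end_to_saug == 59
        assert rec.dist_stop_start_to_saug == 62

    def test_family2_inframe_extension(self, fixture_model):
        alt = _mut(fixture_model, "c.-255G>A")
        rec = delineate_orf(fixture_model, -255, sequence=alt)
        assert rec.kind is OrfKind.INFRAME_EXTENSION
        assert rec.extension_codons == 85
        assert rec.stop_first is None and rec.length_nt is None

    def test_engineered_stop_shortens_extension_to_uorf(self, fixture_model):
        alt = _mut(fixture_model, "c.-255G>A", "c.-75C>T")
        rec = delineate_orf(fixture_model, -255, sequence=alt)
        assert rec.kind is OrfKind.UORF
        assert rec.codons_incl_stop == 61

    def test_missing_aug_rejected(self, fixture_model):
        with pytest.raises(ValueError, match="no ATG"):
            delineate_orf(fixture_model, -263)


class TestDiffUaugEvents:
    def test_creation(self, fixture_model):
        d = diff_uaug_events(fixture_model, _mut(fixture_model, "c.-263C>A"))
        assert [u.start for u in d.created] == [-263]
        assert d.created[0].frame_offset == 2
        assert not (d.destroyed or d.uorf_stop_created or d.uorf_stop_destroyed)

    def test_inert_variant(self, fixture_model):
        d = diff_uaug_events(fixture_model, _mut(fixture_model, "c.-281G>T"))
        assert d.is_empty()

    def test_stop_created_in_existing_uorf_frame(self, fixture_model):
        base_seq = _mut(fixture_model, "c.-263C>A")
        base = TranscriptModel(id="mut", sequence=base_seq, utr5_length=300)
        d = diff_uaug_events(base, apply_variants(base, [parse_hgvs_c("c.-252T>A")]))
        assert [(s.aug, s.stop_first, s.stop_last) for s in d.uorf_stop_created] == [
            (-263, -254, -252)
        ]
        assert not (d.created or d.destroyed or d.uorf_stop_destroyed)

    def test_length_mismatch_rejected(self, fixture_model):
        with pytest.raises(ValueError, match="length mismatch"):
            diff_uaug_events(fixture_model, fixture_model.sequence[:-1])


class TestOracleEquivalence:
    """delineate_orf agrees with brute-force triplet enumeration on 1000
    seeded random transcripts (leaders 50-400 nt)."""

    KIND = {
        OrfKind.UORF: "uORF",
        OrfKind.INFRAME_EXTENSION: "extension",
        OrfKind.OVERLAPPING_OORF: "oORF",
    }

    def test_agreement_on_random_leaders(self):
        checked = 0
        for i in range(1000):
            utr = 50 + (i * 7) % 351
            m = random_transcript(utr_len=utr, gc_fraction=0.45, seed=20_000 + i)
            for start in find_leader_augs(m):
                rec = delineate_orf(m, start)
                exp = oracle_delineate(m.sequence, utr, c_to_index(m, start))
                assert self.KIND[rec.kind] == exp["kind"], (i, start)
                if rec.kind is OrfKind.UORF:
                    assert c_to_index(m, rec.stop_first) == exp["stop_index"]
                    assert rec.codons_incl_stop == exp["codons_incl_stop"]
                    self._arithmetic_identities(rec)
                elif rec.kind is OrfKind.INFRAME_EXTENSION:
                    assert rec.extension_codons == exp["extension_codons"]
                    assert rec.extension_codons == abs(rec.start) // 3
                elif exp["stop_index"] is not None:
                    assert c_to_index(m, rec.stop_first) == exp["stop_index"]
                else:
                    assert rec.stop_first is None
                checked += 1
        assert checked > 1000  # plenty of AUGs actually exercised

    @staticmethod
    def _arithmetic_identities(rec):
        assert rec.codons_incl_stop * 3 == rec.length_nt
        assert rec.length_nt == abs(rec.start) - abs(rec.stop_last) + 1
        assert rec.dist_stop_end_to_saug == abs(rec.stop_last) - 1
        assert rec.dist_stop_start_to_saug == abs(rec.stop_first)
        # the two distance conventions differ by the stop codon's 3 bases
        assert rec.dist_stop_start_to_saug - rec.dist_stop_end_to_saug == 3
        # stop is in frame with its start
        assert (abs(rec.start) - abs(rec.stop_first)) % 3 == 0
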