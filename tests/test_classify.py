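"""Morphology key, ITS2 class rules and cyto-nuclear verdict logic."""
import itertools

import pytest

from amphihap.classify import (
    AMBIGUOUS,
    EvidenceBundle,
    HybridVerdict,
    MorphologyRecord,
    call_its2_class,
    call_morphology,
    classify_sample,
    cohort_report,
)
from amphihap.errors import InputError, SpecError
from amphihap.its2 import HaplotypeProfile
from amphihap.pipeline import default_reference_profiles


def morph(inflorescence, flared, leaf, height, sample="s"):
    return MorphologyRecord(
        sample_id=sample,
        inflorescence=inflorescence,
        flared_ocreae=flared,
        leaf_shape=leaf,
        height=height,
    )


def profile(counts, total=None, catalog=("Type1", "US1", "Type2a", "Type2d", "US2", "US3", "US4")):
    total = sum(counts.values()) if total is None else total
    return HaplotypeProfile(
        sample_id="s", counts=counts, total_spanning=total, catalog_names=catalog
    )


class TestMorphologyKey:
    def test_tall_terrestrial_form(self):
        # long cylindrical inflorescence, no flared ocreae, >30 cm
        assert call_morphology(
            morph("long_cylindrical", False, "lanceolate", "over_30cm")
        ) == "coccinea"

    def test_short_aquatic_form(self):
        assert call_morphology(
            morph("short_ovoid", True, "lanceolate", "under_30cm")
        ) == "stipulacea"

    def test_conflicting_fields_are_ambiguous(self):
        assert call_morphology(
            morph("long_cylindrical", False, "lanceolate", "under_30cm")
        ) == AMBIGUOUS
        assert call_morphology(
            morph("short_ovoid", False, "oblong", "over_30cm")
        ) == AMBIGUOUS

    def test_unknown_vocabulary_rejected(self):
        with pytest.raises(InputError):
            morph("conical", False, "lanceolate", "over_30cm")


class TestIts2Class:
    refs = default_reference_profiles()

    def test_two_diagnostic_haplotypes_only(self):
        assert call_its2_class(profile({"Type1": 600, "US1": 400}), self.refs) == "stipulacea"

    def test_multihaplotype_with_diagnostics_is_northern(self):
        p = profile({"Type1": 300, "US1": 150, "Type2a": 250, "Type2d": 150, "US2": 150})
        assert call_its2_class(p, self.refs) == "coccinea_northern"

    def test_multihaplotype_lacking_diagnostics_is_southern(self):
        p = profile({"Type2a": 340, "Type2d": 220, "US2": 180, "US3": 140, "US4": 120})
        assert call_its2_class(p, self.refs) == "coccinea_southern"

    def test_no_coverage_is_ambiguous(self):
        assert call_its2_class(profile({}, total=0), self.refs) == AMBIGUOUS

    def test_bray_curtis_fallback_to_nearest_reference(self):
        # three haplotypes incl. diagnostics: no diagnostic rule fires
        p = profile({"Type1": 500, "US1": 300, "Type2a": 200})
        assert call_its2_class(p, self.refs) == "stipulacea"
        p2 = profile({"Type1": 260, "Type2a": 400, "Type2d": 340})
        assert call_its2_class(p2, self.refs) == "coccinea_northern"

    def test_distant_profile_is_ambiguous(self):
        p = profile({"US4": 950, "US3": 50})
        # falls through rules (2 haplotypes, not the diagnostic pair) and is
        # far from every reference composition
        assert call_its2_class(p, self.refs, distance_cutoff=0.5) == AMBIGUOUS


def oracle_classify(morph_call, plastid_call, its2_call):
    """Naive re-statement of the verdict rule over collapsed taxon labels."""
    to_taxon = lambda c: (
        "coccinea" if c.startswith("coccinea") else c if c == "stipulacea" else AMBIGUOUS
    )
    calls = {
        "morphology": to_taxon(morph_call),
        "plastid": to_taxon(plastid_call),
        "its2": to_taxon(its2_call),
    }
    det = {k: v for k, v in calls.items() if v != AMBIGUOUS}
    if not det:
        return AMBIGUOUS
    if len(set(det.values())) == 1:
        return "parental"
    if calls["plastid"] == AMBIGUOUS:
        return AMBIGUOUS
    return "hybrid"


class TestClassifySample:
    def test_table_style_bundles(self):
        # a coccinea-looking plant carrying the stipulacea plastome
        v = classify_sample(
            EvidenceBundle("GF", "coccinea", "stipulacea", "coccinea_northern")
        )
        assert v.status == "hybrid"
        assert v.maternal_parent == "stipulacea"
        assert "plastid" in v.discordant_channels
        # concordant parental
        v2 = classify_sample(
            EvidenceBundle("SC2", "coccinea", "coccinea", "coccinea_southern")
        )
        assert v2.status == "parental" and v2.parental_taxon == "coccinea"
        # ITS2-only discordance still counts as hybrid
        v3 = classify_sample(
            EvidenceBundle("SC3", "stipulacea", "stipulacea", "coccinea_northern")
        )
        assert v3.status == "hybrid"
        assert v3.maternal_parent == "stipulacea"
        assert v3.discordant_channels == ("its2",)

    def test_matches_exhaustive_oracle(self):
        labels_mp = ["stipulacea", "coccinea", AMBIGUOUS]
        labels_its = ["stipulacea", "coccinea_northern", "coccinea_southern", AMBIGUOUS]
        for m, p, i in itertools.product(labels_mp, labels_mp, labels_its):
            v = classify_sample(EvidenceBundle("s", m, p, i))
            assert v.status == oracle_classify(m, p, i), (m, p, i)
            if v.status == "hybrid":
                assert v.maternal_parent == p
            if v.status == "parental":
                assert v.discordant_channels == ()

    def test_never_parental_with_determinate_disagreement(self):
        labels_mp = ["stipulacea", "coccinea", AMBIGUOUS]
        labels_its = ["stipulacea", "coccinea_northern", "coccinea_southern", AMBIGUOUS]
        for m, p, i in itertools.product(labels_mp, labels_mp, labels_its):
            to_taxon = lambda c: "coccinea" if c.startswith("coccinea") else c
            det = {to_taxon(c) for c in (m, p, i) if c != AMBIGUOUS}
            if len(det) >= 2:
                assert classify_sample(EvidenceBundle("s", m, p, i)).status != "parental"

    def test_ambiguous_channel_lowers_confidence(self):
        v = classify_sample(EvidenceBundle("s", "coccinea", "coccinea", AMBIGUOUS))
        assert v.status == "parental" and v.low_confidence

    def test_unknown_label_rejected(self):
        with pytest.raises(InputError):
            classify_sample(EvidenceBundle("s", "viridis", "coccinea", "stipulacea"))


class TestCohortReport:
    def _table3_bundles(self):
        rows = [
            ("GF", "coccinea", "stipulacea", "coccinea_northern"),
            ("LA", "coccinea", "stipulacea", "coccinea_northern"),
            ("SL", "coccinea", "stipulacea", "coccinea_northern"),
            ("SC1", "coccinea", "stipulacea", "coccinea_northern"),
            ("SC2", "coccinea", "coccinea", "coccinea_southern"),
            ("SC3", "stipulacea", "stipulacea", "coccinea_northern"),
            ("SC4", "stipulacea", "stipulacea", "stipulacea"),
        ]
        return [EvidenceBundle(*row) for row in rows]

    def test_hybrid_swarm_counts(self, tmp_path):
        """Five hybrids and the two parentals in the mixed-population table."""
        bundles = self._table3_bundles()
        verdicts = [classify_sample(b) for b in bundles]
        df = cohort_report(verdicts, bundles, out_path=tmp_path / "verdicts.tsv")
        counts = df.verdict.value_counts().to_dict()
        assert counts == {"hybrid": 5, "parental": 2}
        parentals = set(df[df.verdict == "parental"]["sample"])
        assert parentals == {"SC2", "SC4"}
        # every hybrid here has the stipulacea plastome, hence maternal parent
        assert set(df[df.verdict == "hybrid"]["maternal_parent"]) == {"stipulacea"}
        footer = (tmp_path / "verdicts.tsv").read_text()
        assert "# hybrid\t5" in footer and "# parental\t2" in footer

    def test_all_concordant_cohort_has_no_hybrids(self):
        bundles = [
            EvidenceBundle(f"s{i}", "coccinea", "coccinea", "coccinea_northern")
            for i in range(5)
        ]
        verdicts = [classify_sample(b) for b in bundles]
        df = cohort_report(verdicts, bundles)
        assert (df.verdict == "parental").all()

    def test_input_order_invariance(self):
        bundles = self._table3_bundles()
        verdicts = [classify_sample(b) for b in bundles]
        df = cohort_report(verdicts, bundles)
        flipped = cohort_report(list(reversed(verdicts)), bundles)
        assert df.set_index("sample").sort_index().equals(
            flipped.set_index("sample").sort_index()
        )

    def test_empty_rejected(self):
        with pytest.raises(SpecError):
            cohort_report([])


class TestVerdictInvariants:
    def test_hybrid_requires_maternal_parent(self):
        with pytest.raises(SpecError):
            HybridVerdict(sample_id="s", status="hybrid")

    def test_parental_cannot_be_discordant(self):
        with pytest.raises(SpecError):
            HybridVerdict(
                sample_id="s",
                status="parental",
                parental_taxon="coccinea",
                discordant_channels=("its2",),
            )
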