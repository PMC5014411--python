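import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gvpid import masses
from gvpid import synthetic_data as sd
from gvpid.gvp_filter import (
    FilterConfig,
    alt_allele_fragment_filter,
    alternative_peptides,
    apply_all,
    confusable_filter,
    evaluable_catalog,
    frequency_filter,
    precursor_mass_filter,
    ptm_filter,
    score_filter,
    uniqueness_filter,
)
from gvpid.io_formats import PsmRecord
from gvpid.variant_reference import GvpCatalogEntry, ProteinRecord, SnpRecord, enumerate_gvps

from _oracles import oracle_b_ion, oracle_y_ion

CONFIG = FilterConfig()


def make_psm(**kw):
    defaults = dict(
        subject_id="S1", sample_id="s", peptide="AAGGK", engine="xtandem",
        score=-5.0, observed_mass=500.0, theoretical_mass=500.0,
    )
    defaults.update(kw)
    return PsmRecord(**defaults)


def make_entry(**kw):
    defaults = dict(
        peptide="AAGGK", gene="G1", protein_accession="P1",
        rs_ids=("rs1",), alleles=(("rs1", "T", "G"),), start=1, end=5,
        allele_class="variant", missed_cleavages=0,
    )
    defaults.update(kw)
    return GvpCatalogEntry(**defaults)


class TestScoreFilter:
    @pytest.mark.parametrize(
        "engine,score,passed",
        [
            ("xtandem", -3.1, True),
            ("xtandem", -2.0, True),   # boundary kept
            ("xtandem", -1.5, False),
            ("mascot", 0.04, True),
            ("mascot", 0.05, True),    # boundary kept
            ("mascot", 0.06, False),
        ],
    )
    def test_thresholds(self, engine, score, passed):
        decision = score_filter(make_psm(engine=engine, score=score), CONFIG)
        assert decision.passed is passed
        if not passed:
            assert decision.failed_rules == ("score",)


class TestPrecursorMassFilter:
    @pytest.mark.parametrize(
        "delta,passed", [(0.25, False), (0.0, True), (0.2, True), (-0.21, False)]
    )
    def test_tolerance(self, delta, passed):
        psm = make_psm(observed_mass=500.0 + delta, theoretical_mass=500.0)
        assert precursor_mass_filter(psm, CONFIG).passed is passed


class TestFrequencyFilter:
    def test_rare_everywhere_fails(self):
        freqs = {"rs1": {"EA": 0.003, "AA": 0.002}}
        d = frequency_filter(make_psm(), make_entry(), CONFIG, freqs)
        assert d.failed_rules == ("frequency",)

    def test_common_passes(self):
        freqs = {"rs1": {"EA": 0.05}}
        assert frequency_filter(make_psm(), make_entry(), CONFIG, freqs).passed

    def test_either_population_semantics(self):
        freqs = {"rs1": {"EA": 0.003, "AA": 0.02}}
        assert frequency_filter(make_psm(), make_entry(), CONFIG, freqs).passed

    def test_missing_frequency_fails_closed(self):
        d = frequency_filter(make_psm(), make_entry(), CONFIG, {})
        assert d.failed_rules == ("frequency_missing",)

    def test_restricted_population_list(self):
        config = FilterConfig(populations=("EA",))
        freqs = {"rs1": {"EA": 0.001, "AA": 0.5}}
        assert not frequency_filter(make_psm(), make_entry(), config, freqs).passed


class TestPtmFilter:
    def test_phospho_fails(self):
        psm = make_psm(modifications=((2, 79.96633, "phospho"),))
        assert ptm_filter(psm, CONFIG).failed_rules == ("ptm",)

    def test_carbamidomethyl_passes(self):
        psm = make_psm(modifications=((1, 57.02146, "carbamidomethyl"),))
        assert ptm_filter(psm, CONFIG).passed

    def test_oxidation_deamidation_pass(self):
        psm = make_psm(
            modifications=((1, 15.99491, "oxidation"), (2, 0.98402, "deamidation"))
        )
        assert ptm_filter(psm, CONFIG).passed

    def test_unmodified_passes(self):
        assert ptm_filter(make_psm(), CONFIG).passed


class TestConfusableAndUniqueness:
    def test_confusable_entry_fails(self):
        entry = make_entry(confusable=True, confusable_pair=("N", "D"))
        assert confusable_filter(make_psm(), entry, CONFIG).failed_rules == ("confusable",)

    def test_plain_entry_passes(self):
        assert confusable_filter(make_psm(), make_entry(), CONFIG).passed

    def test_non_unique_fails(self):
        entry = make_entry(unique=False, matched_genes=("KRT81", "KRT86"))
        assert uniqueness_filter(make_psm(), entry, CONFIG).failed_rules == ("uniqueness",)


PEPTIDE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class TestFragmentLadder:
    @given(
        peptide=st.text(alphabet=PEPTIDE_ALPHABET, min_size=2, max_size=30),
    )
    @settings(max_examples=300, deadline=None)
    def test_by_complementarity(self, peptide):
        # y(i) + b(n-i) = neutral precursor mass + 2 protons
        neutral = masses.peptide_neutral_mass(peptide)
        b = masses.b_ions(peptide)
        y = masses.y_ions(peptide)
        n = len(peptide)
        for i in range(1, n):
            assert b[n - i - 1] + y[i - 1] == pytest.approx(
                neutral + 2 * masses.PROTON, abs=1e-6
            )

    @given(peptide=st.text(alphabet=PEPTIDE_ALPHABET, min_size=2, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_matches_substring_mass_oracle(self, peptide):
        b = masses.b_ions(peptide)
        y = masses.y_ions(peptide)
        for i in range(1, len(peptide)):
            assert b[i - 1] == pytest.approx(oracle_b_ion(peptide, i), abs=1e-9)
            assert y[i - 1] == pytest.approx(oracle_y_ion(peptide, i), abs=1e-9)


class TestAltAlleleFragmentFilter:
    @pytest.fixture
    def pair(self):
        proteome = [ProteinRecord("P1", "G1", "KAAADAAAWAK")]
        snp = SnpRecord(
            rs_id="rs1", gene="G1", protein_accession="P1", protein_position=5,
            ref_aa="D", alt_aa="Y", ref_nuc="G", alt_nuc="T",
            allele_freq={"EUR": 0.2},
        )
        catalog = enumerate_gvps(proteome, [snp], max_missed=0)
        detected = next(e for e in catalog if e.allele_class == "variant")
        other = next(e for e in catalog if e.allele_class == "reference")
        return detected, other, catalog

    def test_alternative_allele_ion_fails(self, pair):
        detected, other, catalog = pair
        own = masses.fragment_ladder(detected.peptide)
        diagnostic = [
            m for m in masses.fragment_ladder(other.peptide)
            if not any(abs(m - o) <= CONFIG.fragment_tol_da for o in own)
        ]
        psm = make_psm(peptide=detected.peptide, fragment_mzs=(diagnostic[0] + 0.01,))
        d = alt_allele_fragment_filter(psm, detected, CONFIG, catalog)
        assert d.failed_rules == ("alt_fragment",)

    def test_shared_ions_pass(self, pair):
        detected, other, catalog = pair
        # b-ions N-terminal of the SAP are identical between alleles
        shared = masses.b_ions(detected.peptide)[:2]
        psm = make_psm(peptide=detected.peptide, fragment_mzs=tuple(shared))
        assert alt_allele_fragment_filter(psm, detected, CONFIG, catalog).passed

    def test_no_fragment_list_flagged_not_evaluated(self, pair):
        detected, _, catalog = pair
        d = alt_allele_fragment_filter(make_psm(), detected, CONFIG, catalog)
        assert d.passed
        assert any("not-evaluated" in f for f in d.flags)

    def test_cleavage_site_sap_uses_full_ladder_diff(self):
        proteome = [ProteinRecord("P1", "G1", "AAARGGGK")]
        snp = SnpRecord(
            rs_id="rsR", gene="G1", protein_accession="P1", protein_position=4,
            ref_aa="R", alt_aa="Q", ref_nuc="G", alt_nuc="A",
            allele_freq={"EUR": 0.2},
        )
        catalog = enumerate_gvps(proteome, [snp], max_missed=0)
        detected = next(e for e in catalog if e.allele_class == "variant")
        alts = alternative_peptides(detected, catalog)
        assert alts == ["AAAR"]
        ref_y1 = masses.y_ions("AAAR")[0]  # R not in the variant ladder
        psm = make_psm(peptide=detected.peptide, fragment_mzs=(ref_y1,))
        d = alt_allele_fragment_filter(psm, detected, CONFIG, catalog)
        assert d.failed_rules == ("alt_fragment",)


class TestApplyAll:
    def test_all_passing_identity(self, clean_study):
        truth = sd.simulate_subjects(clean_study.config, clean_study.snps)
        psms = sd.simulate_detections(truth, clean_study)
        freqs = {s.rs_id: dict(s.allele_freq) for s in clean_study.snps}
        detections, decisions, audit = apply_all(
            psms, clean_study.catalog, CONFIG, freqs
        )
        assert len(detections) == len(psms)
        assert int(audit["n_failed"].sum()) == 0

    def test_multi_rule_psm_excluded_once_both_logged(self):
        psm = make_psm(score=-1.0, observed_mass=501.0)
        entry = make_entry()
        freqs = {"rs1": {"EUR": 0.3}}
        detections, decisions, audit = apply_all([psm], [entry], CONFIG, freqs)
        assert detections == []
        failed = [d for d in decisions if not d.passed]
        assert len(failed) == 1
        assert set(failed[0].failed_rules) == {"score", "precursor_mass"}
        counts = dict(zip(audit["rule"], audit["n_failed"]))
        assert counts["score"] == 1 and counts["precursor_mass"] == 1

    def test_rule_order_permutation_invariant(self, study, rng):
        """Filters are pure; the pass set is invariant under rule order."""
        truth = sd.simulate_subjects(study.config, study.snps)
        psms = sd.simulate_detections(truth, study, include_decoys=True)
        freqs = {s.rs_id: dict(s.allele_freq) for s in study.snps}
        from gvpid.gvp_filter import evaluate_psm

        by_peptide = {}
        for e in study.catalog:
            by_peptide.setdefault(e.peptide, []).append(e)
        baseline = {
            id(psm): evaluate_psm(psm, entry, CONFIG, freqs, study.catalog).failed_rules
            for psm in psms[:40]
            for entry in by_peptide.get(psm.peptide, [])[:1]
        }
        rules = [
            lambda p, e: score_filter(p, CONFIG),
            lambda p, e: precursor_mass_filter(p, CONFIG),
            lambda p, e: frequency_filter(p, e, CONFIG, freqs),
            lambda p, e: ptm_filter(p, CONFIG),
            lambda p, e: confusable_filter(p, e, CONFIG),
            lambda p, e: uniqueness_filter(p, e, CONFIG),
            lambda p, e: alt_allele_fragment_filter(p, e, CONFIG, study.catalog),
        ]
        shuffler = random.Random(7)
        for _ in range(5):
            shuffler.shuffle(rules)
            for psm in psms[:40]:
                entries = by_peptide.get(psm.peptide, [])[:1]
                for entry in entries:
                    failed = sorted(
                        {r for rule in rules for r in rule(psm, entry).failed_rules}
                    )
                    assert tuple(failed) == baseline[id(psm)]

    def test_audit_accounts_for_every_exclusion(self, study):
        truth = sd.simulate_subjects(study.config, study.snps)
        psms = sd.simulate_detections(truth, study, include_decoys=True)
        freqs = {s.rs_id: dict(s.allele_freq) for s in study.snps}
        _, decisions, audit = apply_all(psms, study.catalog, CONFIG, freqs)
        total_from_decisions = sum(len(d.failed_rules) for d in decisions)
        assert int(audit["n_failed"].sum()) == total_from_decisions
        assert all(d.failed_rules for d in decisions if not d.passed)


class TestEvaluableCatalog:
    def test_excludes_rare_confusable_and_shared(self, study):
        freqs = {s.rs_id: dict(s.allele_freq) for s in study.snps}
        ev = evaluable_catalog(study.catalog, CONFIG, freqs)
        rs_present = {rs for e in ev for rs in e.rs_ids}
        assert "rs9001" not in rs_present  # rare
        assert "rs9002" not in rs_present  # confusable
        assert all(e.unique and not e.confusable for e in ev)
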