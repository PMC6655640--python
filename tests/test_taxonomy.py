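"""Percent identity, alignment trimming, and species demarcation."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycovir.errors import (
    AlphabetMismatch,
    DuplicateLabel,
    RaggedAlignment,
    UnknownFamily,
    UnknownTaxon,
)
from mycovir.taxonomy import (
    SpeciesCandidate,
    assign_genome_class,
    default_rules,
    demarcate,
    identity_matrix,
    pairwise_identity,
    trim_alignment,
    _subst,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _oracle_identity(a: str, b: str, alphabet: str = "aa"):
    """Exhaustive affine-gap global aligner (recursive, memoized), written
    independently of the package DP; same scoring and tie preference
    (substitution, then gap consuming ``a``, then gap consuming ``b``)."""
    from mycovir.taxonomy import AA_SCORING, NT_SCORING

    sc = AA_SCORING if alphabet == "aa" else NT_SCORING
    go = sc["gap_open"] + sc["gap_extend"]
    ge = sc["gap_extend"]
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # best score aligning a[:i], b[:j], ending in `state`
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        if state == "M":
            if i == 0 or j == 0:
                return NEG
            s = _subst(a[i - 1], b[j - 1], alphabet)
            return s + max(best(i - 1, j - 1, "M"), best(i - 1, j - 1, "X"),
                           best(i - 1, j - 1, "Y"))
        if state == "X":  # gap in b, consumes a
            if i == 0:
                return NEG
            return max(best(i - 1, j, "M") - go, best(i - 1, j, "X") - ge,
                       best(i - 1, j, "Y") - go)
        if j == 0:
            return NEG
        return max(best(i, j - 1, "M") - go, best(i, j - 1, "Y") - ge,
                   best(i, j - 1, "X") - go)

    n, m = len(a), len(b)
    states = ("M", "X", "Y")
    state = max(states, key=lambda s: best(n, m, s))
    i, j = n, m
    identical = aligned = 0
    while i > 0 or j > 0:
        target = best(i, j, state)
        if state == "M":
            if a[i - 1] == b[j - 1]:
                identical += 1
            aligned += 1
            s = _subst(a[i - 1], b[j - 1], alphabet)
            prevs = [("M", best(i - 1, j - 1, "M") + s),
                     ("X", best(i - 1, j - 1, "X") + s),
                     ("Y", best(i - 1, j - 1, "Y") + s)]
            i, j = i - 1, j - 1
        elif state == "X":
            prevs = [("M", best(i - 1, j, "M") - go),
                     ("X", best(i - 1, j, "X") - ge),
                     ("Y", best(i - 1, j, "Y") - go)]
            i -= 1
        else:
            prevs = [("M", best(i, j - 1, "M") - go),
                     ("Y", best(i, j - 1, "Y") - ge),
                     ("X", best(i, j - 1, "X") - go)]
            j -= 1
        if i == 0 and j == 0:
            break
        for st_, val in prevs:
            if abs(val - target) < 1e-9:
                state = st_
                break
    score = max(best(n, m, s) for s in states)
    return score, 100.0 * identical / aligned if aligned else 0.0


class TestPairwiseIdentity:
    def test_identical_is_100(self):
        assert pairwise_identity("MKVLILACDE", "MKVLILACDE") == 100.0

    def test_two_mismatches_in_ten(self):
        # W/F and Y/F substitutions score positively, so no gaps open
        assert pairwise_identity("MKVLWYACDE", "MKVLFFACDE") == 80.0

    def test_nt_alphabet(self):
        assert pairwise_identity("ACGTACGT", "ACGTTCGT", "nt") == 87.5

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), int(rng.integers(5, 25))))
            b = "".join(rng.choice(list(AA), int(rng.integers(5, 25))))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = "".join(rng.choice(list(AA), int(rng.integers(6, 30))))
        b = "".join(rng.choice(list(AA), int(rng.integers(6, 30))))
        # canonical argument order, as the implementation sorts internally
        if len(a) > len(b) or (len(a) == len(b) and a > b):
            a, b = b, a
        score, ident = _oracle_identity(a, b)
        assert pairwise_identity(a, b) == pytest.approx(ident)

    def test_alphabet_checked(self):
        with pytest.raises(AlphabetMismatch):
            pairwise_identity("ACGT", "ACG*", "nt")


class TestIdentityMatrix:
    SEQS = [("a", "MKVLILACDE"), ("b", "MKVLILACDE"), ("c", "WWWPPPGGHH")]

    def test_symmetry_and_diagonal(self):
        m = identity_matrix(self.SEQS)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)
        assert m.values[0, 1] == 100.0
        assert m.values[0, 2] < 30.0

    def test_permutation_consistency(self):
        m1 = identity_matrix(self.SEQS)
        m2 = identity_matrix(self.SEQS[::-1])
        assert m1.values[0, 2] == m2.values[2, 0]
        assert m2.labels == ["c", "b", "a"]

    def test_entries_equal_pairwise_calls(self):
        m = identity_matrix(self.SEQS)
        for i in range(3):
            for j in range(3):
                assert m.values[i, j] == pytest.approx(
                    pairwise_identity(self.SEQS[i][1], self.SEQS[j][1]))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(DuplicateLabel):
            identity_matrix([("a", "MKVL"), ("a", "MKVI")])


class TestTrimAlignment:
    def test_gap_in_one_of_ten_rows_retained(self):
        msa = ["AC-T"] + ["ACGT"] * 9
        assert trim_alignment(msa, 0.9) == msa

    def test_gap_in_two_of_ten_rows_removed(self):
        msa = ["AC-T", "AC-T"] + ["ACGT"] * 8
        trimmed = trim_alignment(msa, 0.9)
        assert trimmed == ["ACT", "ACT"] + ["ACT"] * 8

    def test_gap_free_unchanged(self):
        msa = ["ACGT", "TGCA"]
        assert trim_alignment(msa, 0.9) == msa

    def test_threshold_extremes(self):
        msa = ["A-GT", "AC-T", "ACG-"]
        assert trim_alignment(msa, 0.0) == msa
        assert trim_alignment(msa, 1.0) == ["A", "A", "A"]

    def test_ragged_rejected(self):
        with pytest.raises(RaggedAlignment):
            trim_alignment(["ACG", "AC"])


class TestRules:
    def test_chrysovirus_cp_threshold(self):
        rules = default_rules()
        assert rules["Chrysovirus"].cp_threshold == 53
        assert rules["Chrysovirus"].rdrp_threshold == 70

    def test_every_rule_requires_host(self):
        assert all(r.host_required for r in default_rules().values())

    def test_at_least_thirteen_taxa(self):
        assert len(default_rules()) >= 13

    def test_le_comparators_where_quoted(self):
        rules = default_rules()
        assert not rules["Fusarivirus"].strict
        assert not rules["Alphapartitivirus"].strict
        assert rules["Victorivirus"].strict


class TestDemarcate:
    def test_victorivirus_same_host_high_identity_is_known(self):
        call = demarcate(SpeciesCandidate(
            "Victorivirus", {"rdrp": 97, "cp": 98},
            host="Penicillium digitatum KH8",
            known_hosts=["Penicillium digitatum Pd1"]))
        assert call.status == "known_species"

    def test_gammapartitivirus_congeneric_host_is_known(self):
        call = demarcate(SpeciesCandidate(
            "Gammapartitivirus", {"rdrp": 95, "cp": 95},
            host="Penicillium digitatum HS-F6",
            known_hosts=["Penicillium stoloniferum"]))
        assert call.status == "known_species"
        assert call.related_genus_advisory

    def test_alphapartitivirus_low_identity_new_host_is_new(self):
        call = demarcate(SpeciesCandidate(
            "Alphapartitivirus", {"rdrp": 40, "cp": 30},
            host="Clohesyomyces aquaticus CBS 115471",
            known_hosts=["Rosellinia necatrix", "Vicia faba"]))
        assert call.status == "new_species"

    def test_alphapartitivirus_passes_at_equality(self):
        call = demarcate(SpeciesCandidate(
            "Alphapartitivirus", {"rdrp": 90, "cp": 80},
            host="Grosmannia clavigera", known_hosts=["Vicia faba"]))
        assert call.status == "new_species"

    def test_victorivirus_fails_at_equality(self):
        call = demarcate(SpeciesCandidate(
            "Victorivirus", {"rdrp": 90, "cp": 70},
            host="Hortaea werneckii", known_hosts=["Hortaea werneckii"]))
        assert call.status == "known_species"

    def test_alternavirus_is_indeterminate(self):
        call = demarcate(SpeciesCandidate(
            "Alternavirus", {"rdrp": 93}, host="Aspergillus heteromorphus",
            known_hosts=["Aspergillus foetidus"]))
        assert call.status == "indeterminate"

    def test_unknown_taxon(self):
        with pytest.raises(UnknownTaxon):
            demarcate(SpeciesCandidate("Bornavirus", {"rdrp": 10},
                                       "x", []))

    @given(
        rdrp=st.floats(0, 100), cp=st.floats(0, 100),
        drop=st.floats(0, 50),
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_under_identity_decrease(self, rdrp, cp, drop):
        base = SpeciesCandidate("Gammapartitivirus",
                                {"rdrp": rdrp, "cp": cp},
                                host="Penicillium digitatum",
                                known_hosts=["Penicillium stoloniferum"])
        lower = SpeciesCandidate("Gammapartitivirus",
                                 {"rdrp": max(0.0, rdrp - drop),
                                  "cp": max(0.0, cp - drop)},
                                 host=base.host, known_hosts=base.known_hosts)
        before = demarcate(base).status
        after = demarcate(lower).status
        if before == "new_species":
            assert after == "new_species"
        # lowering identities must never create a known_species call
        if before != "known_species":
            assert after != "known_species"


class TestGenomeClass:
    @pytest.mark.parametrize(
        "family,cls",
        [
            ("Partitiviridae", "dsRNA"),
            ("Hypoviridae", "(+)ssRNA"),
            ("Ambiguiviridae", "ssRNA"),
            ("Mitovirus", "(+)ssRNA"),
            ("Tobamo-like virus", "(+)ssRNA"),
            ("Unclassified dsRNA", "dsRNA"),
        ],
    )
    def test_lookup(self, family, cls):
        assert assign_genome_class(family) == cls

    def test_unknown_family(self):
        with pytest.raises(UnknownFamily):
            assign_genome_class("Adenoviridae")
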