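"""Signature intersection, decomposition, maintenance and specificity."""

import numpy as np
import pytest

from intestsig.meta_signature import (
    DirectionalGeneSet,
    MetaProfile,
    build_meta_profile,
    chi_square_2x2,
    decompose_signature,
    derive_reference_signature,
    maintenance_analysis,
    round_half_away,
    specificity_fraction,
)

from conftest import gene_set


def closed_form_chi2(a, b, c, d):
    """2x2 Pearson chi-square oracle: N(ad-bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def expected_counts_chi2(table):
    """Brute-force Pearson statistic from expected counts."""
    t = np.asarray(table, dtype=float)
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return float(((t - exp) ** 2 / exp).sum())


def random_profile(rng, genes):
    return DirectionalGeneSet(
        entries={g: ("up" if u else "down") for g, u in zip(genes, rng.random(len(genes)) < 0.5)}
    )


class TestReferenceSignature:
    def test_concordant_gene_kept_with_direction(self):
        sig = derive_reference_signature(
            gene_set(VIL1="up", TP63="down", CDX2="up"),
            gene_set(VIL1="up", TP63="down", CDX2="down"),
        )
        assert sig.entries == {"VIL1": "up", "TP63": "down"}

    def test_discordant_gene_excluded(self):
        sig = derive_reference_signature(gene_set(MUC2="up"), gene_set(MUC2="down"))
        assert len(sig) == 0

    def test_disjoint_inputs_empty(self):
        assert len(derive_reference_signature(gene_set(A="up"), gene_set(B="up"))) == 0


class TestMetaProfile:
    def test_unanimous_gene_included(self):
        mp = build_meta_profile([gene_set(A="up"), gene_set(A="up"), gene_set(A="up")])
        assert mp.entries.entries == {"A": "up"}
        assert len(mp.member_studies) == 3

    def test_dissent_excludes_under_all_concordant(self):
        mp = build_meta_profile([gene_set(A="up"), gene_set(A="up"), gene_set(A="down")])
        assert "A" not in mp.entries

    def test_majority_rule_allows_absence_but_not_dissent(self):
        sets = [gene_set(A="up", B="up"), gene_set(A="up"), gene_set(B="down")]
        mp = build_meta_profile(sets, rule="majority_concordant")
        assert mp.entries.entries == {"A": "up"}  # B is 2v1 by presence but has dissent

    def test_all_concordant_subset_of_majority(self, rng):
        genes = [f"g{i}" for i in range(60)]
        sets = []
        for _ in range(3):
            chosen = [g for g, keep in zip(genes, rng.random(60) < 0.6) if keep]
            sets.append(random_profile(rng, chosen))
        strict = build_meta_profile(sets, rule="all_concordant")
        loose = build_meta_profile(sets, rule="majority_concordant")
        assert strict.genes() <= loose.genes()
        for g in strict.genes():
            assert strict.entries.direction_of(g) == loose.entries.direction_of(g)

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            build_meta_profile([])
        with pytest.raises(ValueError, match=">= 2"):
            build_meta_profile([gene_set(A="up")])


class TestDecomposition:
    def test_reported_fraction_matches_printed_style(self):
        """A 989-gene disease profile with 768 reference-like members is 77.7%."""
        disease = {f"d{i}": "up" for i in range(989)}
        reference = gene_set(**{f"d{i}": "up" for i in range(768)})
        decomp = decompose_signature(DirectionalGeneSet(entries=disease), reference)
        assert len(decomp.reference_like) == 768
        assert len(decomp.non_reference) == 221
        assert decomp.fraction_reference_like_1dp == 77.7

    def test_disjoint_gives_zero(self):
        decomp = decompose_signature(gene_set(A="up", B="down"), gene_set(C="up"))
        assert decomp.fraction_reference_like == 0.0
        assert decomp.non_reference.genes() == {"A", "B"}

    def test_subset_gives_hundred(self):
        decomp = decompose_signature(gene_set(A="up"), gene_set(A="up", B="down"))
        assert decomp.fraction_reference_like == 100.0

    def test_direction_mismatch_controlled_by_flag(self):
        disease = gene_set(A="up")
        reference = gene_set(A="down")
        assert decompose_signature(disease, reference).fraction_reference_like == 0.0
        relaxed = decompose_signature(disease, reference, require_direction_match=False)
        assert relaxed.fraction_reference_like == 100.0

    def test_partition_property(self, rng):
        genes = [f"g{i}" for i in range(200)]
        disease = random_profile(rng, genes)
        reference = random_profile(rng, rng.choice(genes, 80, replace=False))
        decomp = decompose_signature(disease, reference)
        assert len(decomp.reference_like) + len(decomp.non_reference) == len(disease)
        assert decomp.reference_like.genes() | decomp.non_reference.genes() == disease.genes()
        assert not (decomp.reference_like.genes() & decomp.non_reference.genes())

    def test_monotone_in_reference(self, rng):
        genes = [f"g{i}" for i in range(100)]
        disease = random_profile(rng, genes)
        small = {g: disease.entries[g] for g in genes[:20]}
        big = {**small, **{g: disease.entries[g] for g in genes[20:50]}}
        f_small = decompose_signature(
            disease, DirectionalGeneSet(entries=small)
        ).fraction_reference_like
        f_big = decompose_signature(
            disease, DirectionalGeneSet(entries=big)
        ).fraction_reference_like
        assert f_big >= f_small

    def test_empty_disease_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            decompose_signature(DirectionalGeneSet(), gene_set(A="up"))


class TestMaintenance:
    def build(self, n_like, n_kept_like, n_non, n_kept_non):
        disease = {f"L{i}": "up" for i in range(n_like)}
        disease.update({f"N{i}": "up" for i in range(n_non)})
        reference = gene_set(**{f"L{i}": "up" for i in range(n_like)})
        later = {f"L{i}": "up" for i in range(n_kept_like)}
        later.update({f"N{i}": "up" for i in range(n_kept_non)})
        decomp = decompose_signature(DirectionalGeneSet(entries=disease), reference)
        return maintenance_analysis(decomp, DirectionalGeneSet(entries=later))

    def test_printed_style_maintenance_fractions(self):
        """769 intestine-like genes with 652 kept: 84.8% (85% at 0 dp)."""
        result = self.build(769, 652, 220, 45)
        assert result.table.tolist() == [[652, 117], [45, 175]]
        assert result.fractions_1dp["reference_like"] == 84.8
        assert round_half_away(result.fractions["reference_like"], 0) == 85.0
        assert result.fractions_1dp["non_reference"] == 20.5
        assert result.p < 1e-4

    def test_diagonal_table_chi2(self):
        result = self.build(10, 10, 10, 0)
        assert result.table.tolist() == [[10, 0], [0, 10]]
        assert result.chi2 == pytest.approx(20.0)

    def test_everything_maintained_gives_zero_association(self):
        result = self.build(8, 8, 5, 5)
        assert result.fractions["reference_like"] == 100.0
        assert result.fractions["non_reference"] == 100.0
        # components indistinguishable: no association
        assert result.chi2 == 0.0
        assert result.p == 1.0

    def test_direction_flip_counts_as_lost(self):
        decomp = decompose_signature(gene_set(A="up", B="up"), gene_set(A="up", B="up"))
        later = gene_set(A="up", B="down")
        result = maintenance_analysis(decomp, later)
        assert result.maintained["reference_like"] == {"A"}
        assert result.lost["reference_like"] == {"B"}


class TestChiSquare:
    def test_agrees_with_closed_form_on_random_tables(self, rng):
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 500, size=4)
            chi2, p = chi_square_2x2([[a, b], [c, d]])
            assert chi2 == pytest.approx(closed_form_chi2(a, b, c, d), abs=1e-9, rel=1e-9)

    def test_agrees_with_expected_count_formula(self, rng):
        for _ in range(50):
            t = rng.integers(1, 100, size=(2, 2))
            chi2, _ = chi_square_2x2(t)
            assert chi2 == pytest.approx(expected_counts_chi2(t), abs=1e-9)

    def test_zero_margin_flagged_absent(self):
        assert chi_square_2x2([[0, 0], [3, 4]]) == (None, None)

    def test_yates_option_reduces_statistic(self):
        plain, _ = chi_square_2x2([[20, 10], [10, 20]])
        corrected, _ = chi_square_2x2([[20, 10], [10, 20]], yates=True)
        assert corrected < plain


class TestSpecificity:
    def test_fraction_by_definition(self):
        profile = DirectionalGeneSet(entries={f"p{i}": "up" for i in range(100)})
        signature = gene_set(**{f"p{i}": "up" for i in range(13)}, **{"x": "down"})
        frac, chi2, p = specificity_fraction(signature, profile)
        assert frac == 13.0
        assert chi2 is None

    def test_subset_is_hundred(self):
        profile = gene_set(A="up", B="down")
        frac, _, _ = specificity_fraction(gene_set(A="up", B="down", C="up"), profile)
        assert frac == 100.0

    def test_empty_signature_is_zero(self):
        frac, _, _ = specificity_fraction(DirectionalGeneSet(), gene_set(A="up"))
        assert frac == 0.0

    def test_comparator_split_tested(self):
        profile = DirectionalGeneSet(entries={f"p{i}": "up" for i in range(100)})
        signature = gene_set(**{f"p{i}": "up" for i in range(13)})
        frac, chi2, p = specificity_fraction(signature, profile, comparator_split=(769, 220))
        assert frac == 13.0
        assert chi2 == pytest.approx(closed_form_chi2(13, 87, 769, 220))
        assert p < 1e-5


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(77.6542, 77.7), (77.75, 77.8), (84.78, 84.8), (-0.05, -0.1), (26.85, 26.9)]
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value, 1) == expected
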