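"""Polymorphism profiles, the Ti/Tv kernel and the effective space."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyspace import (
    MutationModel,
    PolymorphismProfile,
    SemantideSpec,
    build_substitution_matrix,
    effective_space,
    profile_from_alignment,
    space_log_size,
)
from polyspace.constrained_space import site_stationary_distributions


class TestSubstitutionMatrix:
    def test_uniform_kernel_at_kappa_one(self):
        p = build_substitution_matrix(0.3, 1.0)
        off = p[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_biased_kernel_splits_mu_by_kappa(self):
        p = build_substitution_matrix(0.3, 4.0)
        # A(0) -> G(2) is the transition; A -> C(1), A -> T(3) transversions
        assert p[0, 2] == pytest.approx(0.3 * 4 / 6)
        assert p[0, 1] == pytest.approx(0.05)
        assert p[0, 3] == pytest.approx(0.05)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_extreme_bias_leaves_only_transitions(self):
        p = build_substitution_matrix(0.3, 1e12)
        assert p[0, 2] == pytest.approx(0.3, rel=1e-9)  # A -> G
        assert p[1, 3] == pytest.approx(0.3, rel=1e-9)  # C -> T
        assert p[0, 1] < 1e-10

    @settings(max_examples=100, deadline=None)
    @given(mu=st.floats(1e-6, 0.99), kappa=st.floats(1e-3, 1e3))
    def test_rows_sum_to_one_and_total_rate_is_mu(self, mu, kappa):
        p = build_substitution_matrix(mu, kappa)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(1.0 - np.diag(p), mu, atol=1e-12)

    @pytest.mark.parametrize("mu, kappa", [(-0.1, 1), (1.0, 1), (0.5, 0), (0.5, -2)])
    def test_invalid_parameters_rejected(self, mu, kappa):
        with pytest.raises(ValueError):
            build_substitution_matrix(mu, kappa)


class TestProfileFromAlignment:
    def test_observed_sets_and_frequencies(self):
        prof = profile_from_alignment(["ACGT", "ACGA"])
        sets = prof.allowed_sets()
        assert sets[:3] == [frozenset("A"), frozenset("C"), frozenset("G")]
        assert sets[3] == frozenset("TA")
        assert prof.frequencies[3, 0] == pytest.approx(0.5)  # A
        assert prof.frequencies[3, 3] == pytest.approx(0.5)  # T
        assert prof.n_variable == 1

    def test_identical_sequences_are_all_invariant(self):
        prof = profile_from_alignment(["ACGT"] * 5)
        assert prof.n_variable == 0

    def test_rna_and_case_are_normalised(self):
        prof = profile_from_alignment(["acgu", "ACGT"])
        assert prof.n_variable == 0

    def test_sequence_order_is_irrelevant(self):
        seqs = ["ACGT", "ACGA", "TCGA"]
        a = profile_from_alignment(seqs)
        b = profile_from_alignment(seqs[::-1])
        assert np.array_equal(a.allowed, b.allowed)
        assert np.allclose(a.frequencies, b.frequencies)

    @pytest.mark.parametrize(
        "seqs",
        [["ACGT"], ["ACGT", "ACG"], ["ACGT", "AC-T"], ["ACGT", "ACNT"], []],
    )
    def test_malformed_alignments_rejected(self, seqs):
        with pytest.raises(ValueError):
            profile_from_alignment(seqs)

    def test_tsv_round_trip(self, tmp_path):
        prof = profile_from_alignment(["ACGT", "ACGA", "TCGA"])
        path = tmp_path / "profile.tsv"
        prof.to_tsv(path)
        back = PolymorphismProfile.from_tsv(path)
        assert np.array_equal(back.allowed, prof.allowed)
        assert np.allclose(back.frequencies, prof.frequencies, atol=1e-6)


class TestEffectiveSpace:
    def test_free_unbiased_space_equals_naive_space(self):
        prof = PolymorphismProfile.free(10)
        eff = effective_space(prof, MutationModel(mu=1e-3, kappa=1.0))
        assert eff.le == 10
        assert eff.ke == pytest.approx(4.0)
        assert eff.log10_size == pytest.approx(
            space_log_size(SemantideSpec.dna(10)), rel=1e-12
        )

    def test_fully_invariant_gene_has_identity_space(self):
        prof = profile_from_alignment(["ACGT"] * 3)
        eff = effective_space(prof, MutationModel(mu=1e-3, kappa=4.0))
        assert eff.le == 0
        assert eff.log10_size == 0.0

    def test_transition_pair_site_has_effective_base_two(self):
        # site 1 invariant {A}; site 2 allows the transition pair {A, G}
        allowed = np.array([[1, 0, 0, 0], [1, 0, 1, 0]], dtype=bool)
        freqs = allowed / allowed.sum(axis=1, keepdims=True)
        prof = PolymorphismProfile(allowed=allowed, frequencies=freqs)
        eff = effective_space(prof, MutationModel(mu=1e-3, kappa=1e9))
        assert eff.le == 1
        assert eff.ke == pytest.approx(2.0, rel=1e-6)
        # enumeration: the reachable space is {A, G} at that site -> 2 states
        assert 10**eff.log10_size == pytest.approx(2.0, rel=1e-6)

    def test_bias_shrinks_the_effective_base_monotonically(self):
        prof = PolymorphismProfile.free(5)
        kes = [
            effective_space(prof, MutationModel(mu=1e-3, kappa=k)).ke
            for k in (1.0, 2.0, 4.0, 10.0, 1e6)
        ]
        assert all(a > b for a, b in zip(kes, kes[1:]))
        assert kes[0] == pytest.approx(4.0)
        assert kes[-1] == pytest.approx(2.0, rel=1e-4)

    @settings(max_examples=50, deadline=None)
    @given(
        kappa=st.floats(0.5, 100),
        seed=st.integers(0, 10_000),
    )
    def test_effective_space_never_exceeds_naive_space(self, kappa, seed):
        rng = np.random.default_rng(seed)
        L = 8
        allowed = rng.random((L, 4)) < 0.6
        allowed[np.arange(L), rng.integers(0, 4, L)] = True  # non-empty
        freqs = allowed / allowed.sum(axis=1, keepdims=True)
        prof = PolymorphismProfile(allowed=allowed, frequencies=freqs)
        eff = effective_space(prof, MutationModel(mu=1e-3, kappa=kappa))
        assert 1.0 <= eff.ke <= 4.0 + 1e-12
        assert eff.log10_size <= space_log_size(SemantideSpec.dna(L)) + 1e-12


def test_restricted_kernel_stationary_is_uniform_on_allowed():
    """Rejection preserves the kernel's symmetry, so each site's stationary
    law is uniform over its allowed set regardless of kappa."""
    allowed = np.array(
        [[1, 0, 0, 0], [1, 0, 1, 0], [1, 1, 1, 0], [1, 1, 1, 1]], dtype=bool
    )
    freqs = allowed / allowed.sum(axis=1, keepdims=True)
    prof = PolymorphismProfile(allowed=allowed, frequencies=freqs)
    pis = site_stationary_distributions(prof, MutationModel(mu=0.01, kappa=7.0))
    for i in range(4):
        k = allowed[i].sum()
        assert np.allclose(pis[i, allowed[i]], 1.0 / k, atol=1e-9)
        assert np.allclose(pis[i, ~allowed[i]], 0.0, atol=1e-12)
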