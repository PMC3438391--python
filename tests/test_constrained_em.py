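"""Constrained EM: compatible pairs, spanning, fitting, list augmentation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kirpop as kp
from kirpop.constrained_em import SpanningError
from kirpop.kir_data import FRAMEWORK_LOCI, GenotypeProfile, PopulationSample


def brute_force_pairs(g, H):
    """Independent oracle: enumerate every (i <= j) pair, no prefiltering."""
    He = H.expand()
    return tuple(
        (i, j)
        for i, j in itertools.combinations_with_replacement(range(len(He)), 2)
        if He[i].markers | He[j].markers == g.present)


def grid_search_loglik(pair_sets, n_hap, step):
    """Independent oracle: maximize the multinomial log-likelihood over a
    frequency grid on the simplex (vectorized over grid points)."""
    axes = np.arange(0.0, 1.0 + step / 2, step)
    if n_hap == 2:
        grids = np.stack([axes, 1.0 - axes], axis=1)
    elif n_hap == 3:
        f1, f2 = np.meshgrid(axes, axes, indexing="ij")
        keep = f1 + f2 <= 1.0 + 1e-12
        grids = np.stack([f1[keep], f2[keep], 1.0 - f1[keep] - f2[keep]],
                         axis=1)
    else:
        raise ValueError("oracle supports 2 or 3 haplotypes")
    grids = np.clip(grids, 0.0, 1.0)
    ll = np.zeros(len(grids))
    for count, pairs in pair_sets:
        prob = np.zeros(len(grids))
        for i, j in pairs:
            factor = 1.0 if i == j else 2.0
            prob += factor * grids[:, i] * grids[:, j]
        with np.errstate(divide="ignore"):
            ll += count * np.log(prob)
    return float(np.nanmax(ll[np.isfinite(ll)]))


def make_pop(patterns_with_counts, name="toy", region="Europe"):
    genotypes = []
    k = 0
    for pattern, count in patterns_with_counts:
        for _ in range(count):
            genotypes.append(GenotypeProfile(f"i{k}", frozenset(pattern)))
            k += 1
    return PopulationSample(name, region, 46.0, 2.0, tuple(genotypes))


class TestCompatiblePairs:
    def test_aa_homozygote_has_unique_explanation(self, h8, h18):
        by = dict(zip(h18.names, h18))
        g = kp.genotype_from_pair(by["cA-tA"], by["cA-tA"])
        cps = kp.compatible_pairs(g, h8)
        names = {(h18.names[i], h18.names[j]) for i, j in cps.pairs}
        assert names == {("cA-tA", "cA-tA")}

    def test_cAtA_x_cB1tB_pair_is_found(self, h8, h18):
        by = dict(zip(h18.names, h18))
        g = kp.genotype_from_pair(by["cA-tA"], by["cB1-tB.2DS3.2DS5"])
        cps = kp.compatible_pairs(g, h8)
        names = {(h18.names[i], h18.names[j]) for i, j in cps.pairs}
        assert ("cA-tA", "cB1-tB.2DS3.2DS5") in names

    def test_unspanned_genotype_gives_empty_set(self, h8):
        g = GenotypeProfile("odd", FRAMEWORK_LOCI | {"2DS3"})
        assert not kp.compatible_pairs(g, h8).spanned

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, h18, data):
        """For small sublists the constrained search equals brute force."""
        idx = data.draw(st.lists(st.integers(0, 17), min_size=1, max_size=4,
                                 unique=True))
        H = kp.AprioriHaplotypeSet(tuple(h18[i] for i in idx))
        i = data.draw(st.integers(0, len(H) - 1))
        j = data.draw(st.integers(0, len(H) - 1))
        g = kp.genotype_from_pair(H[i], H[j])
        assert kp.compatible_pairs(g, H).pairs == brute_force_pairs(g, H)


class TestSpanningCheck:
    def test_aa_population_is_spanned_by_seven_list(self, h7, h18):
        spec = kp.PopulationSpec("p", "Europe", 46, 2, 10, {"cA-tA": 1.0})
        pop = kp.simulate_panel([spec], h18, seed=0)["p"]
        report = kp.spanning_check(pop, h7)
        assert report.all_spanned and report.unresolved_fraction == 0.0

    def test_missing_framework_locus_is_unspanned(self, h8, h18):
        by = dict(zip(h18.names, h18))
        full = kp.genotype_from_pair(by["cA-tA"], by["cA-tA"]).present
        pop = make_pop([(full - {"2DL4"}, 1)])
        report = kp.spanning_check(pop, h8)
        assert not report.all_spanned
        with pytest.raises(SpanningError, match="must be increased"):
            kp.spanning_check(pop, h8, sharp=True)

    def test_simulated_panels_are_always_spanned(self, h8, h18, worldwide_truth):
        _, gen = worldwide_truth
        specs = [kp.PopulationSpec(f"p{i}", "Africa", 0, 0, 40, gen)
                 for i in range(3)]
        panel = kp.simulate_panel(specs, h18, seed=123)
        for pop in panel:
            assert kp.spanning_check(pop, h8).all_spanned


class TestEmFit:
    def test_monomorphic_population_fixed_point(self, h8, h18):
        spec = kp.PopulationSpec("p", "Europe", 46, 2, 8, {"cA-tA": 1.0})
        pop = kp.simulate_panel([spec], h18, seed=0)["p"]
        est = kp.em_fit(pop, h8)
        assert est.frequencies["cA-tA"] == pytest.approx(1.0)
        assert est.log_likelihood == pytest.approx(0.0, abs=1e-6)

    def test_unambiguous_data_equals_direct_counting(self, h18):
        """One A/A homozygote plus one individual whose only explanation is
        {A, B}: 3 of 4 chromosomes are A."""
        by = dict(zip(h18.names, h18))
        A, B = by["cA-tA"], by["cB2-tA"]
        pop = make_pop([(kp.genotype_from_pair(A, A).present, 1),
                        (kp.genotype_from_pair(A, B).present, 1)])
        H = kp.AprioriHaplotypeSet((A, B))
        est = kp.em_fit(pop, H)
        assert est.frequencies["cA-tA"] == pytest.approx(0.75, abs=1e-9)
        assert est.frequencies["cB2-tA"] == pytest.approx(0.25, abs=1e-9)

    def test_ambiguous_toy_matches_grid_search(self, h18):
        """EM's optimum matches a brute-force likelihood grid (0.001 step)."""
        by = dict(zip(h18.names, h18))
        A, B2, B1 = by["cA-tA"], by["cB2-tA"], by["cB1-tA.2DS3"]
        H = kp.AprioriHaplotypeSet((A, B2, B1))
        # B1 union B2 == B1 markers ∪ {nothing new}? build a panel mixing
        # unambiguous and ambiguous profiles
        patterns = [
            (kp.genotype_from_pair(A, A).present, 3),
            (kp.genotype_from_pair(A, B2).present, 2),
            (kp.genotype_from_pair(B1, B2).present, 2),
            (kp.genotype_from_pair(A, B1).present, 1),
        ]
        pop = make_pop(patterns)
        est = kp.em_fit(pop, H)
        pair_sets = []
        for pattern, count in pop.distinct_genotypes().items():
            cps = kp.compatible_pairs(GenotypeProfile("g", pattern), H)
            pair_sets.append((count, cps.pairs))
        oracle = grid_search_loglik(pair_sets, 3, step=0.001)
        assert est.log_likelihood >= oracle - 1e-6

    def test_sharp_mode_raises_on_unspanned(self, h8, h18):
        by = dict(zip(h18.names, h18))
        full = kp.genotype_from_pair(by["cA-tA"], by["cA-tA"]).present
        pop = make_pop([(full, 3), (full - {"2DL4"}, 1)])
        with pytest.raises(SpanningError):
            kp.em_fit(pop, h8, kp.EMConfig(mode="sharp"))

    def test_lenient_mode_reports_unresolved_fraction(self, h8, h18):
        by = dict(zip(h18.names, h18))
        full = kp.genotype_from_pair(by["cA-tA"], by["cA-tA"]).present
        pop = make_pop([(full, 3), (full - {"2DL4"}, 1)])
        est = kp.em_fit(pop, h8, kp.EMConfig(mode="lenient"))
        assert est.unresolved_fraction == pytest.approx(0.25)
        assert est.frequencies["cA-tA"] == pytest.approx(1.0)

    def test_loglik_trace_monotone_and_frequencies_normalized(
            self, h8, h18, worldwide_truth):
        _, gen = worldwide_truth
        spec = kp.PopulationSpec("p", "Europe", 46, 2, 120, gen)
        pop = kp.simulate_panel([spec], h18, seed=77)["p"]
        est = kp.em_fit(pop, h8, kp.EMConfig(restarts=3, seed=9))
        tr = est.log_likelihood_trace
        assert all(b >= a - 1e-9 for a, b in zip(tr, tr[1:]))
        assert sum(est.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_restarts_do_not_worsen_likelihood(self, h8, h18, worldwide_truth):
        _, gen = worldwide_truth
        spec = kp.PopulationSpec("p", "Europe", 46, 2, 60, gen)
        pop = kp.simulate_panel([spec], h18, seed=5)["p"]
        single = kp.em_fit(pop, h8, kp.EMConfig(restarts=1))
        multi = kp.em_fit(pop, h8, kp.EMConfig(restarts=4, seed=2))
        assert multi.log_likelihood >= single.log_likelihood - 1e-9


class TestAugmentMinimal:
    def test_already_spanned_panel_adds_nothing(self, h8, h18, worldwide_truth):
        _, gen = worldwide_truth
        spec = kp.PopulationSpec("p", "Europe", 46, 2, 50, gen)
        panel = kp.simulate_panel([spec], h18, seed=8)
        assert kp.augment_minimal(panel, h8) == []

    def test_deletion_homozygote_recruits_deletion_haplotype(self, h7, h18):
        """A panel with a Cen-B1~Tel-B-minus-3DS1 homozygote forces the 3DS1
        deletion haplotype into the list."""
        by = dict(zip(h18.names, h18))
        delhom = kp.genotype_from_pair(by["cB1-tBdel.2DS3.2DS5"],
                                       by["cB1-tBdel.2DS3.2DS5"])
        pop = make_pop([(delhom.present, 1)])
        panel = kp.StudyPanel((pop,))
        added = kp.augment_minimal(panel, h7)
        assert added, "augmentation should add at least one haplotype"
        assert all("3DS1" not in h.markers and h.cen_motif == "Cen-B1"
                   for h in added)

    def test_greedy_at_least_as_large_as_exhaustive_minimum(self, h18):
        """Greedy set-cover size >= the exact minimum over <=10 candidates."""
        by = dict(zip(h18.names, h18))
        base = kp.AprioriHaplotypeSet((by["cA-tA"],))
        cand_names = ["cA-tB.2DS5", "cB1-tA.2DS3", "cB2-tA", "cB2-tB.2DS5",
                      "cB3-tA.2DS5", "cB1-tB.2DS3.2DS5"]
        candidates = kp.AprioriHaplotypeSet(tuple(by[n] for n in cand_names))
        patterns = [
            (kp.genotype_from_pair(by["cA-tA"], by["cB2-tA"]).present, 2),
            (kp.genotype_from_pair(by["cB2-tB.2DS5"], by["cB2-tB.2DS5"]).present, 1),
            (kp.genotype_from_pair(by["cA-tA"], by["cB3-tA.2DS5"]).present, 1),
        ]
        panel = kp.StudyPanel((make_pop(patterns),))
        added = kp.augment_minimal(panel, base, candidates)
        # every genotype spanned afterwards
        final = kp.AprioriHaplotypeSet(tuple(base.expand()) + tuple(added))
        assert kp.spanning_check(panel.populations[0], final).all_spanned
        # exhaustive minimal subset
        best = None
        for r in range(len(cand_names) + 1):
            for combo in itertools.combinations(cand_names, r):
                trial = kp.AprioriHaplotypeSet(
                    tuple(base.expand()) + tuple(by[n] for n in combo))
                if kp.spanning_check(panel.populations[0], trial).all_spanned:
                    best = r
                    break
            if best is not None:
                break
        assert len(added) >= best
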