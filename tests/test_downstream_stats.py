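import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from progulons import AnnotationCollection, OmicsGroupSpec, simulate_paired_omics
from progulons.downstream_stats import (
    PairedOmics,
    annotation_enrichment,
    conservation_of_coregulation,
    contribution_rho,
    group_coordination,
    group_permutation_test,
    group_stats,
    same_chromosome_enrichment,
    scale_of_variation,
)


def fisher_greater_oracle(a, b, c, d):
    """Hypergeometric tail by explicit enumeration (enrichment side)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(a, min(row1, col1) + 1):
        if row1 - k > n - col1:
            continue
        p += (math.comb(col1, k) * math.comb(n - col1, row1 - k)
              / math.comb(n, row1))
    return p


class TestAnnotationEnrichment:
    def make_ann(self, sizes):
        sets = {}
        start = 0
        for i, s in enumerate(sizes):
            sets[f"set{i}"] = {f"g{j}" for j in range(start, start + s)}
            start += s
        universe = {f"g{j}" for j in range(start)}
        return AnnotationCollection.from_sets(sets, universe)

    def test_small_sets_excluded(self):
        ann = self.make_ann([19, 25])
        analysed = [f"g{j}" for j in range(44)]
        out = annotation_enrichment({"grp": analysed[:10]}, ann, analysed,
                                    min_set_size=20)
        assert set(out["set"]) == {"set1"}

    def test_bonferroni_arithmetic(self):
        ann = self.make_ann([25, 25, 25, 25, 25])
        analysed = [f"g{j}" for j in range(125)]
        out = annotation_enrichment({"grp": analysed[:30]}, ann, analysed)
        assert len(out) == 5
        np.testing.assert_allclose(out["p_bonferroni"],
                                   np.minimum(out["p_raw"] * 5, 1.0))

    def test_fisher_matches_enumeration_oracle(self):
        """The (8,2,12,178) contingency table yields exactly the
        hypergeometric tail probability."""
        ann = AnnotationCollection.from_sets(
            {"path": {f"g{j}" for j in range(20)}},
            {f"g{j}" for j in range(200)})
        analysed = [f"g{j}" for j in range(200)]
        group = [f"g{j}" for j in range(8)] + [f"g{j}" for j in range(20, 22)]
        out = annotation_enrichment({"grp": group}, ann, analysed,
                                    min_set_size=10)
        assert out.loc[0, "p_raw"] == pytest.approx(
            fisher_greater_oracle(8, 2, 12, 178), rel=1e-12)


class TestContributionRho:
    def paired(self, mrna, protein):
        cols = [f"s{i}" for i in range(mrna.shape[1])]
        idx = pd.Index([f"g{i}" for i in range(mrna.shape[0])], name="gene_id")
        return PairedOmics(pd.DataFrame(mrna, index=idx, columns=cols),
                           pd.DataFrame(protein, index=idx, columns=cols))

    def test_identity_and_reversal(self):
        x = np.linspace(0, 1, 8)[None, :]
        po = self.paired(np.vstack([x, x]), np.vstack([x, -x]))
        assert contribution_rho(po, "g0") == pytest.approx(1.0)
        assert contribution_rho(po, "g1") == pytest.approx(-1.0)

    def test_coupling_orders_cohorts(self):
        """Median mRNA-to-protein rho is higher for strongly coupled
        gene groups in nearly every simulation."""
        wins = 0
        for rs in range(20):
            po, truth = simulate_paired_omics(
                n_genes=60, n_samples=30,
                groups={
                    "hi": OmicsGroupSpec(size=25, coupling=0.9,
                                         protein_noise_sd=0.3),
                    "lo": OmicsGroupSpec(size=25, coupling=0.1,
                                         protein_noise_sd=0.3),
                },
                rng_seed=rs)
            med = {}
            for name in ("hi", "lo"):
                rhos = [contribution_rho(po, g)
                        for g in truth.module_members[name]]
                med[name] = np.median(rhos)
            wins += med["hi"] > med["lo"]
        assert wins >= 19


class TestGroupPermutationTest:
    def test_minimum_attainable_p(self):
        stat = pd.Series(np.arange(100, dtype=float),
                         index=[f"g{i}" for i in range(100)])
        group = [f"g{i}" for i in range(95, 100)]  # the 5 largest values
        p = group_permutation_test(stat, group, stat.index, B=200, side="high",
                                   rng_seed=0)
        assert p == pytest.approx(1 / 201)

    def test_group_equals_universe(self):
        stat = pd.Series(np.random.default_rng(0).normal(size=50),
                         index=[f"g{i}" for i in range(50)])
        p = group_permutation_test(stat, stat.index, stat.index, B=100)
        assert p == 1.0

    def test_power_on_shifted_group(self):
        """A group shifted by one SD is detected (P < 0.05) in nearly
        every replicate at B = 200."""
        hits = 0
        for rs in range(20):
            rng = np.random.default_rng(rs)
            vals = rng.normal(size=120)
            vals[:20] += 1.0
            stat = pd.Series(vals, index=[f"g{i}" for i in range(120)])
            p = group_permutation_test(stat, [f"g{i}" for i in range(20)],
                                       stat.index, B=200, rng_seed=rs)
            hits += p < 0.05
        assert hits >= 18

    def test_monotone_invariance(self):
        """P is unchanged under strictly increasing transforms of the
        per-gene statistic."""
        rng = np.random.default_rng(3)
        vals = rng.normal(size=60)
        stat = pd.Series(vals, index=[f"g{i}" for i in range(60)])
        group = [f"g{i}" for i in range(10)]
        p1 = group_permutation_test(stat, group, stat.index, B=300, rng_seed=9)
        p2 = group_permutation_test(np.exp(stat), group, stat.index, B=300,
                                    rng_seed=9)
        assert p1 == p2

    def test_group_larger_than_universe(self):
        stat = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            group_permutation_test(stat, ["a", "b", "c"], ["a", "b"])


class TestGroupCoordination:
    def test_shared_latent_no_noise(self):
        z = np.random.default_rng(0).normal(size=20)
        df = pd.DataFrame([z, 2 * z, z - 1], index=["a", "b", "c"])
        assert group_coordination(df, ["a", "b", "c"]) == pytest.approx(1.0)

    def test_independent_rows_near_zero(self):
        extreme = 0
        for rs in range(20):
            rng = np.random.default_rng(rs)
            df = pd.DataFrame(rng.normal(size=(6, 30)),
                              index=[f"g{i}" for i in range(6)])
            med = group_coordination(df, list(df.index))
            extreme += abs(med) >= 0.2
        assert extreme <= 1

    def test_planted_rho_recovered(self):
        from progulons import ModuleSpec, simulate_proteomehd
        devs = []
        for rs in range(5):
            m, truth = simulate_proteomehd(
                40, 60, [ModuleSpec.from_rho(20, 0.6)], rng_seed=rs)
            med = group_coordination(m.values,
                                     truth.module_members["module_1"])
            devs.append(med)
        assert np.median(devs) == pytest.approx(0.6, abs=0.1)


class TestConservation:
    def rho_frame(self, n, seed, planted=None):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-0.2, 0.9, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        if planted:
            for i, j in planted:
                r[i, j] = r[j, i] = 0.8
        ids = [f"g{i}" for i in range(n)]
        return pd.DataFrame(r, index=ids, columns=ids)

    def test_identity_dataset_fully_conserved(self):
        a = self.rho_frame(10, 0)
        b = a.copy()
        b.index = b.columns = [f"m{i}" for i in range(10)]
        omap = {f"g{i}": f"m{i}" for i in range(10)}
        membership = {"g0": "prog1", "g1": "prog1", "g2": "prog2"}
        table, p = conservation_of_coregulation(a, b, omap, membership)
        tested = table[table["total"] > 0]
        assert (tested["fraction"] == 1.0).all()

    def test_same_progulon_pairs_conserved_more(self):
        """When only same-progulon pairs keep their co-regulation in the
        second dataset, category (same) conservation exceeds the others
        about two-fold and the Fisher test is significant."""
        n = 30
        same_pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        a = self.rho_frame(n, 1, planted=same_pairs
                           + [(10 + i, 20 + i) for i in range(8)])
        b = self.rho_frame(n, 2, planted=same_pairs)
        b.index = b.columns = [f"m{i}" for i in range(n)]
        omap = {f"g{i}": f"m{i}" for i in range(n)}
        membership = {f"g{i}": "prog1" for i in range(6)}
        table, p = conservation_of_coregulation(a, b, omap, membership)
        t = table.set_index("category")
        assert t.loc["same_progulon", "fraction"] >= \
            2 * t.loc["no_progulon", "fraction"]
        assert p < 0.05


class TestSameChromosome:
    def test_single_chromosome_group(self):
        cmap = {f"g{i}": ("chr1" if i < 5 else f"chr{i}") for i in range(30)}
        obs, exp, p = same_chromosome_enrichment([f"g{i}" for i in range(5)],
                                                 cmap)
        assert obs == 1.0

    def test_two_equal_chromosomes_expected_half(self):
        n = 200
        cmap = {f"g{i}": ("chrA" if i % 2 == 0 else "chrB") for i in range(n)}
        _, exp, _ = same_chromosome_enrichment(["g0", "g2", "g4"], cmap)
        # exact closed form: (n/2 - 1) / (n - 1) ~ 0.5 for large n
        assert exp == pytest.approx((n / 2 - 1) / (n - 1))
        assert exp == pytest.approx(0.5, abs=0.01)

    def test_random_groups_not_enriched(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(300)]
        cmap = {g: f"chr{rng.integers(1, 23)}" for g in genes}
        sig = 0
        for rs in range(20):
            grp = list(np.random.default_rng(rs).choice(genes, 12,
                                                        replace=False))
            _, _, p = same_chromosome_enrichment(grp, cmap)
            sig += p < 0.05
        assert sig <= 2


class TestScaleOfVariation:
    def test_constant_rows_zero(self):
        df = pd.DataFrame([[1.0] * 5, [3.0] * 5], index=["a", "b"])
        assert scale_of_variation(df, ["a", "b"]) == 0.0

    def test_hand_computed_mad(self):
        df = pd.DataFrame([[-1.0, 0.0, 1.0]], index=["a"])
        assert scale_of_variation(df, ["a"]) == 1.0

    def test_homogeneous_in_scale(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(4, 12)),
                          index=["a", "b", "c", "d"])
        base = scale_of_variation(df, df.index)
        assert scale_of_variation(df * -2.5, df.index) == \
            pytest.approx(2.5 * base)


class TestDecoupling:
    def test_coordination_and_contribution_vary_independently(self):
        """High protein coordination can coexist with low mRNA
        contribution and vice versa (rank-order assertions)."""
        po, truth = simulate_paired_omics(
            n_genes=80, n_samples=36,
            groups={
                # ribosome-like: strong shared latents, no transmission
                "coord": OmicsGroupSpec(size=25, coupling=0.0,
                                        mrna_latent_sd=1.5,
                                        protein_latent_sd=1.5,
                                        protein_noise_sd=0.3),
                # cytoskeleton-like: full transmission, weak latents
                "contrib": OmicsGroupSpec(size=25, coupling=1.0,
                                          mrna_latent_sd=0.4,
                                          mrna_noise_sd=1.0,
                                          protein_noise_sd=0.2),
            },
            rng_seed=4)
        gs = {name: group_stats(po, truth.module_members[name])
              for name in ("coord", "contrib")}
        assert gs["coord"].protein_coordination > gs["contrib"].protein_coordination
        assert gs["coord"].contribution < gs["contrib"].contribution
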