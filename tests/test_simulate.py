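import numpy as np
import pytest
from scipy import stats

from fastbat.ld import compute_ld, prune_by_ld
from fastbat.simulate import (
    ScenarioConfig,
    add_perfect_ld_snp,
    marginal_scan,
    place_clustered_causals,
    power_metric,
    simulate_block_genotypes,
    simulate_lowld_causal_sets,
    simulate_phenotype,
    simulate_scenario,
    simulate_unlinked_genotypes,
    stream,
)

from conftest import make_panel


# ---------------------------------------------------------------------------
# genotype generators
# ---------------------------------------------------------------------------


def test_unlinked_panel_is_deterministic_under_seed():
    a = simulate_unlinked_genotypes(100, 20, seed=3)
    b = simulate_unlinked_genotypes(100, 20, seed=3)
    c = simulate_unlinked_genotypes(100, 20, seed=4)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    assert not np.array_equal(a.genotypes, c.genotypes)


def test_unlinked_genotypes_are_binomial_counts():
    p = simulate_unlinked_genotypes(500, 40, seed=1)
    assert set(np.unique(p.genotypes)) <= {0.0, 1.0, 2.0}
    assert not np.isnan(p.genotypes).any()
    f = p.genotypes.mean(axis=0) / 2
    assert f.min() > 0.0 and f.max() < 1.0
    assert list(p.positions) == list(range(1, 41))


def test_unlinked_mean_absolute_correlation_matches_null_theory():
    # under independence the sample correlation is ~N(0, 1/n), so
    # E|r| = sqrt(2/(pi n))
    n, m = 5000, 300
    p = simulate_unlinked_genotypes(n, m, seed=8)
    r = np.corrcoef(p.genotypes.T)
    off = np.abs(r[np.triu_indices(m, 1)])
    expected = np.sqrt(2 / (np.pi * n))
    assert off.mean() == pytest.approx(expected, rel=0.1)


def test_block_rho_zero_is_unlinked_like():
    p = simulate_block_genotypes(3000, 20, block_size=5, within_block_rho=0.0, seed=2)
    r = np.corrcoef(p.genotypes.T)
    adjacent = np.abs(np.diag(r, 1))
    assert adjacent.mean() < 3 * np.sqrt(2 / (np.pi * 3000))


def test_block_ld_increases_with_rho():
    def mean_adjacent_r2(rho):
        p = simulate_block_genotypes(4000, 30, block_size=5,
                                     within_block_rho=rho, seed=6)
        r = np.corrcoef(p.genotypes.T)
        within = [r[j, j + 1] ** 2 for j in range(29) if (j % 5) != 4]
        return np.mean(within)

    assert mean_adjacent_r2(0.95) > mean_adjacent_r2(0.5) > mean_adjacent_r2(0.0)


def test_block_adjacent_r_matches_thresholded_gaussian_oracle():
    # direct Monte-Carlo of the latent model: two AR(1)-correlated
    # standard normals per haplotype, thresholded at the frequency quantiles
    rho, n = 0.9, 20_000
    panel = simulate_block_genotypes(n, 5, block_size=5, within_block_rho=rho, seed=9)
    freqs = panel.genotypes.mean(axis=0) / 2

    rng = np.random.default_rng(123)
    draws = 10**6
    z1 = rng.standard_normal((draws, 2))
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal((draws, 2))
    for j in range(4):
        t1, t2 = stats.norm.ppf(freqs[j]), stats.norm.ppf(freqs[j + 1])
        g1 = (z1 < t1).sum(axis=1)
        g2 = (z2 < t2).sum(axis=1)
        oracle_r = np.corrcoef(g1, g2)[0, 1]
        realized_r = np.corrcoef(panel.genotypes[:, j], panel.genotypes[:, j + 1])[0, 1]
        assert realized_r == pytest.approx(oracle_r, abs=0.05)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------


def test_null_phenotype_is_pure_noise_with_uniform_scan():
    panel = simulate_unlinked_genotypes(3000, 200, seed=5)
    cohort = simulate_phenotype(panel, [], 0.004, seed=5)
    assert np.var(cohort.phenotype) == pytest.approx(1.0, rel=0.1)
    pvals = [r.pvalue for r in marginal_scan(cohort)]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_each_causal_contributes_target_variance():
    n, h2 = 20_000, 0.02
    panel = simulate_unlinked_genotypes(n, 12, seed=10)
    causals = ["snp3", "snp7", "snp11"]
    idx = panel.snp_index(causals)
    w = panel.genotypes[:, idx]
    w = (w - w.mean(axis=0)) / w.std(axis=0)
    realized = []
    for rep in range(20):
        cohort = simulate_phenotype(panel, causals, h2, seed=100 + rep)
        beta, *_ = np.linalg.lstsq(w, cohort.phenotype, rcond=None)
        # estimation noise inflates beta^2 by ~var(beta_hat) = sigma^2/n
        realized.extend(
            (beta**2 - (1 - 3 * h2) / n) / np.var(cohort.phenotype)
        )
    # realized variance fraction tracks the target with slope 1 within 5%
    assert np.mean(realized) / h2 == pytest.approx(1.0, abs=0.05)


def test_total_heritability_must_stay_below_one():
    panel = simulate_unlinked_genotypes(100, 10, seed=0)
    with pytest.raises(ValueError, match="heritability"):
        simulate_phenotype(panel, panel.snp_ids, 0.11, seed=0)


# ---------------------------------------------------------------------------
# causal placement and perfect-LD augmentation
# ---------------------------------------------------------------------------


def test_clustered_placement_budget_and_geometry():
    panel = simulate_unlinked_genotypes(200, 3000, seed=2)
    panel.positions = np.arange(1, 3001) * 1000  # 3 Mb span
    causals = place_clustered_causals(panel, seed=42)
    assert len(causals) == 50
    assert len(set(causals)) == 50


def test_cluster_size_p_one_fills_first_window():
    panel = simulate_unlinked_genotypes(100, 3000, seed=2)
    panel.positions = np.arange(1, 3001) * 1000
    causals = place_clustered_causals(panel, seed=7, cluster_size_p=1.0)
    pos = np.sort(panel.positions[panel.snp_index(causals)])
    assert len(causals) == 50
    assert pos[-1] - pos[0] < 200_000  # all inside one 200 kb window


def test_cluster_sizes_match_direct_binomial_process():
    # realized mean cluster size vs a direct simulation of the stated
    # process: draw k ~ Binomial(50, 0.1), truncate by the remaining
    # budget, repeat until 50 placed; clusters with k = 0 vanish.
    # A wide panel (50 Mb) keeps 200 kb windows from overlapping often.
    panel = simulate_unlinked_genotypes(50, 5000, seed=1)
    panel.positions = np.arange(1, 5001) * 10_000
    sizes = []
    for seed in range(120):
        causals = place_clustered_causals(panel, seed=seed)
        pos = np.sort(panel.positions[panel.snp_index(causals)])
        n_clusters = 1 + int((np.diff(pos) > 200_000).sum())
        sizes.append(50 / n_clusters)

    rng = np.random.default_rng(99)
    oracle = []
    for _ in range(4000):
        placed, clusters = 0, 0
        while placed < 50:
            k = min(int(rng.binomial(50, 0.1)), 50 - placed)
            if k > 0:
                placed += k
                clusters += 1
        oracle.append(50 / clusters)
    assert np.mean(sizes) == pytest.approx(np.mean(oracle), rel=0.15)


def test_perfect_ld_copy_has_r2_one_and_prunes_to_one():
    panel = simulate_unlinked_genotypes(500, 5, seed=3)
    aug = add_perfect_ld_snp(panel, "snp2", "snp2_dup")
    ld = compute_ld(aug, ["snp2", "snp2_dup"])
    assert ld.r[0, 1] == pytest.approx(1.0)
    kept, removed = prune_by_ld(ld, 0.99)
    assert len(kept) == 1 and len(removed) == 1
    with pytest.raises(ValueError, match="already"):
        add_perfect_ld_snp(aug, "snp2", "snp2_dup")


# ---------------------------------------------------------------------------
# marginal scan
# ---------------------------------------------------------------------------


def test_scan_matches_textbook_least_squares_on_hand_data():
    x = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
    y = np.array([1.1, 1.9, 3.2, 2.1, 0.9])
    cohort = simulate_phenotype(make_panel(x[:, None]), [], 0.004, seed=0)
    cohort.phenotype = y
    rec = marginal_scan(cohort)[0]
    ref = stats.linregress(x, y)
    assert rec.beta == pytest.approx(ref.slope, rel=1e-10)
    assert rec.se == pytest.approx(ref.stderr, rel=1e-10)
    assert rec.pvalue == pytest.approx(ref.pvalue, rel=1e-10)
    assert rec.n == 5 and rec.freq == pytest.approx(0.4)


def test_scan_noncentrality_matches_theory():
    # single causal explaining h2 of variance in n samples: the
    # association chi-squared has noncentrality ~ n*h2, so its mean over
    # replicates is ~ n*h2 + 1
    n, h2, reps = 6000, 0.004, 120
    mean_chisq = []
    for rep in range(reps):
        panel = simulate_unlinked_genotypes(n, 1, seed=500 + rep)
        cohort = simulate_phenotype(panel, ["snp1"], h2, seed=500 + rep)
        rec = marginal_scan(cohort)[0]
        mean_chisq.append((rec.beta / rec.se) ** 2)
    expected = n * h2 + 1
    se = np.sqrt(2 * (1 + 2 * n * h2) / reps)
    assert abs(np.mean(mean_chisq) - expected) < 3 * se


def test_scan_drops_monomorphic_snp():
    g = np.column_stack([np.ones(50), np.arange(50) % 3])
    cohort = simulate_phenotype(make_panel(g), [], 0.004, seed=1)
    recs = marginal_scan(cohort)
    assert [r.snp_id for r in recs] == ["snp2"]


# ---------------------------------------------------------------------------
# power metric and scenario assembly
# ---------------------------------------------------------------------------


def test_power_metric_known_values():
    assert power_metric([0.5]) == pytest.approx(0.4549364, abs=1e-6)
    assert power_metric([0.5, 0.04550026]) == pytest.approx(
        (0.4549364 + 4.0) / 2, abs=1e-5
    )
    rng = np.random.default_rng(0)
    assert power_metric(rng.uniform(size=20_000)) == pytest.approx(1.0, abs=0.05)


def test_power_metric_rejects_out_of_range():
    with pytest.raises(ValueError):
        power_metric([0.0, 0.5])


def test_scenario_layout_keeps_sets_apart_and_seeded():
    cfg = ScenarioConfig(n_samples=200, set_sizes=[10, 15, 12], seed=5)
    cohort, sets = simulate_scenario(cfg)
    assert [len(s.snp_ids) for s in sets] == [10, 15, 12]
    assert len(cohort.causal_snp_ids) == 3  # one per set
    spans = [(s.span_start, s.span_end) for s in sets]
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        assert s2 - e1 > 100_000  # disjoint even with 50 kb windows
    cohort2, _ = simulate_scenario(cfg)
    np.testing.assert_array_equal(cohort.phenotype, cohort2.phenotype)


def test_lowld_causal_sets_structure():
    cohort, sets = simulate_lowld_causal_sets(800, 4, seed=11)
    assert len(sets) == 4
    assert len(cohort.causal_snp_ids) == 4
    for s, causal in zip(sets, cohort.causal_snp_ids):
        assert causal == s.snp_ids[0]
        ld = compute_ld(cohort.panel, s.snp_ids)
        # causal column is unlinked: modest correlation with everything
        assert np.max(ld.r[0, 1:] ** 2) < 0.5
        # the null blocks carry real high-LD redundancy
        assert np.max(ld.r[1:, 1:] ** 2 - np.eye(len(s.snp_ids) - 1)) > 0.8


def test_named_streams_are_independent():
    a = stream(1, "genotypes").standard_normal(5)
    b = stream(1, "effects").standard_normal(5)
    c = stream(1, "genotypes").standard_normal(5)
    np.testing.assert_array_equal(a, c)
    assert not np.array_equal(a, b)
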