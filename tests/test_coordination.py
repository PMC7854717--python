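import numpy as np
import pytest

from gfabric.coordination import (
    classify_pair,
    coordination_table,
    cor_significance,
    df_rule,
    enumerate_pairs,
    n_cross_evaluations,
    n_within_pairs,
    pairwise_cor,
    partner_profile,
    synchrony,
    synchrony_table,
)
from gfabric.io_model import filter_spots, normalize
from gfabric.synthetic import (
    PlantedModule,
    PlantedSynchrony,
    SimulationConfig,
    generate_measurements,
)
from oracles import cor_p_oracle, pearson_oracle, permutation_cor_p

from conftest import CHAMBERS, build_expression_set


# ---------------------------------------------------------------------------
# df rule
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("r,expected", [(1, 2), (2, 6), (3, 10), (13, 50)])
def test_df_rule_equal_redundancy(r, expected):
    assert df_rule(r, r) == expected


def test_df_rule_unequal_redundancy_averages_spots():
    assert df_rule(1, 3) == 2
    assert df_rule(5, 2) == 2


def test_df_rule_rejects_bad_counts():
    with pytest.raises(ValueError):
        df_rule(0, 1)


# ---------------------------------------------------------------------------
# pairwise correlation
# ---------------------------------------------------------------------------


def _pair_expr(vals_a, vals_b, chamber="LA"):
    arrays = {}
    for name, vals in (("a", vals_a), ("b", vals_b)):
        base = {c: np.exp(np.arange(np.atleast_2d(vals).shape[0] * 4).reshape(-1, 4) * 0.1 + 1)
                for c in CHAMBERS}
        base[chamber] = np.atleast_2d(np.asarray(vals, dtype=float))
        arrays[name] = base
    return build_expression_set(arrays)


def test_gene_with_itself_rho_one():
    expr = _pair_expr([1.0, 2.0, 4.0, 8.0], [3.0, 5.0, 7.0, 9.0])
    rho, df = pairwise_cor(expr, "a", "a", "LA")
    assert rho == pytest.approx(1.0)
    assert df == 2


def test_exact_antilinearity_gives_rho_minus_one():
    expr = _pair_expr(2.0 ** np.array([1, 2, 3, 4.0]), 2.0 ** np.array([8, 6, 4, 2.0]))
    rho, df = pairwise_cor(expr, "a", "b", "LA")
    assert rho == pytest.approx(-1.0)
    assert cor_significance(rho, df) == 0.0


def test_mixed_redundancy_averages_spots_df_two():
    vals_a = np.array([[1.0, 2.0, 3.0, 4.0]])
    vals_b = np.array([[2.0, 4.0, 6.0, 8.0], [4.0, 8.0, 12.0, 16.0]])
    expr = _pair_expr(vals_a, vals_b)
    rho, df = pairwise_cor(expr, "a", "b", "LA")
    assert df == 2
    # per-replica averages of b are proportional to a, so log2 correlation is 1
    assert rho == pytest.approx(1.0)


def test_zero_variance_gives_undecided_with_warning():
    expr = _pair_expr([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
    with pytest.warns(UserWarning, match="zero log-variance"):
        rho, df = pairwise_cor(expr, "a", "b", "LA")
    assert np.isnan(rho)
    assert classify_pair(rho, np.nan) == "undecided"


def test_planted_latent_correlation_recovered_mostly():
    # 1000 independent gene pairs, each planted at latent correlation 0.99
    loading = np.sqrt(0.99)
    names = [f"G{i + 1:04d}" for i in range(2000)]
    modules = [
        PlantedModule(f"m{i}", (names[2 * i], names[2 * i + 1]), "LA", loading)
        for i in range(1000)
    ]
    config = SimulationConfig(
        n_genes=2000,
        redundancy_weights={1: 1.0},
        bio_cv_range=(0.3, 0.3),
        tech_cv=0.0,
        planted_modules=modules,
        filter_violation_fraction=0.0,
        seed=1234,
    )
    measurements, _ = generate_measurements(config)
    expr = normalize(measurements)
    rhos = np.array(
        [pairwise_cor(expr, names[2 * i], names[2 * i + 1], "LA")[0] for i in range(1000)]
    )
    assert np.mean((rhos >= 0.9) & (rhos <= 1.0)) >= 0.95


# ---------------------------------------------------------------------------
# significance and classification
# ---------------------------------------------------------------------------


def test_cor_significance_values():
    assert cor_significance(0.0, 2) == pytest.approx(1.0)
    assert cor_significance(1.0, 2) == 0.0
    # critical value of r at alpha = 0.05, df = 2 is 0.950
    assert cor_significance(0.95, 2) == pytest.approx(0.05, abs=1e-4)
    assert cor_significance(0.7, 10) == pytest.approx(cor_p_oracle(0.7, 10), rel=1e-12)


def test_cor_significance_matches_pearsonr_oracle():
    from scipy.stats import pearsonr

    rng = np.random.default_rng(4)
    for n in (4, 8, 12):
        u, v = rng.normal(size=n), rng.normal(size=n)
        rho = pearson_oracle(u, v)
        assert cor_significance(rho, n - 2) == pytest.approx(
            pearsonr(u, v).pvalue, rel=1e-9
        )


@pytest.mark.parametrize(
    "rho,df,expected",
    [
        (0.999, 2, "synergistic"),
        (-0.999, 2, "antagonistic"),
        (0.02, 2, "independent"),
        (0.6, 2, "undecided"),
    ],
)
def test_classify_pair(rho, df, expected):
    assert classify_pair(rho, cor_significance(rho, df)) == expected


def test_permutation_p_rank_ordering_agrees():
    # the exact permutation p at n = 4 takes only multiples of 1/24 and its
    # null depends on each fixture's geometry, so agreement with the analytic
    # t-based p is strong but not pairwise-perfect across fixtures
    from scipy.stats import spearmanr

    rng = np.random.default_rng(99)
    analytic, exact = [], []
    for _ in range(100):
        u, v = rng.normal(size=4), rng.normal(size=4)
        rho = pearson_oracle(u, v)
        analytic.append(cor_significance(rho, 2))
        exact.append(permutation_cor_p(u, v))
    analytic, exact = np.array(analytic), np.array(exact)
    assert spearmanr(analytic, exact).statistic >= 0.9
    ii, jj = np.triu_indices(100, k=1)
    strict = (analytic[ii] != analytic[jj]) & (exact[ii] != exact[jj])
    concordant = np.sign(analytic[ii] - analytic[jj]) == np.sign(exact[ii] - exact[jj])
    assert concordant[strict].mean() >= 0.9


# ---------------------------------------------------------------------------
# all-pairs table and enumeration
# ---------------------------------------------------------------------------


def test_coordination_table_counts_and_consistency(random_fixture_expr):
    genes = random_fixture_expr.genes
    table = coordination_table(random_fixture_expr, "LA")
    assert len(table) == n_within_pairs(len(genes))
    assert len(enumerate_pairs(genes)) == len(table)
    # vectorized table equals the single-pair path, including mixed-R pairs
    rng = np.random.default_rng(0)
    for idx in rng.choice(len(table), size=15, replace=False):
        row = table.iloc[idx]
        rho, df = pairwise_cor(random_fixture_expr, row["gene_a"], row["gene_b"], "LA")
        assert row["rho"] == pytest.approx(rho, rel=1e-10)
        assert row["df"] == df


def test_enumeration_arithmetic_small_n():
    genes = [f"g{i}" for i in range(30)]
    assert n_within_pairs(30) == len(enumerate_pairs(genes)) == 435
    assert n_cross_evaluations(30) == 120


# ---------------------------------------------------------------------------
# synchrony
# ---------------------------------------------------------------------------


def test_synchrony_identical_profiles():
    vals = 2.0 ** np.array([1.0, 3.0, 2.0, 4.0])
    arrays = {"g": {c: np.atleast_2d(vals) for c in CHAMBERS}}
    expr = build_expression_set(arrays)
    edge = synchrony(expr, "g", "LA", "RA")
    assert edge.rho == pytest.approx(1.0)
    assert edge.category == "synergistic"
    assert edge.df == 2


def test_synchrony_reversed_animal_order():
    arrays = {
        "g": {
            "LA": np.atleast_2d(2.0 ** np.array([1.0, 2.0, 3.0, 4.0])),
            "RA": np.atleast_2d(2.0 ** np.array([4.0, 3.0, 2.0, 1.0])),
            "LV": np.full((1, 4), 1.0),
            "RV": np.full((1, 4), 1.0),
        }
    }
    expr = build_expression_set(arrays)
    assert synchrony(expr, "g", "LA", "RA").rho == pytest.approx(-1.0)


def test_synchrony_table_covers_four_adjacencies_and_matches_scalar(random_fixture_expr):
    table = synchrony_table(random_fixture_expr)
    n = len(random_fixture_expr.genes)
    assert len(table) == n_cross_evaluations(n)
    assert set(table["chambers"]) == {"LA-RA", "LV-RV", "LA-LV", "RA-RV"}
    row = table[(table["gene"] == "g03") & (table["chambers"] == "LA-LV")].iloc[0]
    edge = synchrony(random_fixture_expr, "g03", "LA", "LV")
    assert row["rho"] == pytest.approx(edge.rho, rel=1e-10)
    assert row["df"] == edge.df


def test_planted_synchrony_recovery_over_seeds():
    # 30 planted synchronous + 30 independent genes inside a full-size
    # transcriptome background (the median scaling needs many genes to be quiet)
    names = [f"G{i + 1:04d}" for i in range(2000)]
    sens = []
    for seed in range(20):
        planted = [PlantedSynchrony(g, "LA", "RA", 0.995) for g in names[:30]]
        config = SimulationConfig(
            n_genes=2000,
            redundancy_weights={1: 1.0},
            bio_cv_range=(0.3, 0.3),
            tech_cv=0.01,
            planted_synchrony=planted,
            filter_violation_fraction=0.0,
            seed=1000 + seed,
        )
        measurements, _ = generate_measurements(config)
        expr = normalize(measurements)
        table = synchrony_table(expr, (("LA", "RA"),), genes=names[:60])
        hits = table[table["gene"].isin(names[:30])]["synchronous"]
        sens.append(float(hits.mean()))
    assert float(np.mean(sens)) >= 0.9


# ---------------------------------------------------------------------------
# partner profiles
# ---------------------------------------------------------------------------


def test_partner_profile_extremes():
    rng = np.random.default_rng(10)
    base = np.exp(rng.normal(0, 0.5, 4))
    arrays = {"hub": {c: np.atleast_2d(base) for c in CHAMBERS}}
    for i in range(4):
        arrays[f"p{i}"] = {c: np.atleast_2d(base * (i + 2)) for c in CHAMBERS}
    expr = build_expression_set(arrays)
    percent, edges = partner_profile(expr, "hub", [f"p{i}" for i in range(4)], "LA")
    assert percent == 100.0
    assert len(edges) == 4

    # partners with no relationship at all: independent white noise
    arrays = {"hub": {c: np.atleast_2d(np.exp(rng.normal(0, 0.5, 4))) for c in CHAMBERS}}
    for i in range(6):
        arrays[f"q{i}"] = {
            c: np.atleast_2d(np.exp(rng.normal(0, 0.5, 4))) for c in CHAMBERS
        }
    expr = build_expression_set(arrays)
    percent, edges = partner_profile(expr, "hub", [f"q{i}" for i in range(6)], "LA")
    assert 0.0 <= percent <= 100.0 / 6 + 1e-9  # at most one chance hit expected here


def test_partner_profile_planted_fraction():
    # 27 partners, 10 planted co-varying with the hub at loading 0.999
    names = [f"G{i + 1:04d}" for i in range(28)]
    hub, partners = names[0], names[1:]
    percents = []
    for seed in range(10):
        config = SimulationConfig(
            n_genes=28,
            redundancy_weights={1: 1.0},
            bio_cv_range=(0.3, 0.3),
            tech_cv=0.0,
            planted_modules=[
                PlantedModule("hubmod", tuple([hub] + partners[:10]), "LA", 0.999)
            ],
            filter_violation_fraction=0.0,
            seed=500 + seed,
        )
        measurements, _ = generate_measurements(config)
        expr = normalize(measurements)
        percent, edges = partner_profile(expr, hub, partners, "LA")
        assert len(edges) == 27
        percents.append(percent)
    assert np.mean(percents) == pytest.approx(100.0 * 10 / 27, abs=6.0)


def test_partner_profile_requires_quantified_partner(random_fixture_expr):
    from gfabric.io_model import IntegrityError

    with pytest.raises(IntegrityError):
        partner_profile(random_fixture_expr, "g00", ["nope"], "LA")
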