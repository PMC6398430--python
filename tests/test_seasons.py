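"""Season assignment and the resampling test battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crowflock.seasons import (
    SEASONS,
    assign_season,
    bootstrap_friedman,
    bootstrap_wilcoxon_pairs,
    exact_wilcoxon_pairs,
    friedman_chi2,
    monte_carlo_friedman,
    relative_days_seen,
    season_table,
    signed_rank,
    subgroup_size_by_category,
)


@pytest.mark.parametrize(
    "date, season",
    [
        ("2014-03-15", "breeding"),
        ("2014-02-01", "breeding"),
        ("2014-05-31", "breeding"),
        ("2014-06-01", "parental_care"),
        ("2014-09-30", "parental_care"),
        ("2014-10-01", "nonbreeder"),
        ("2015-01-31", "nonbreeder"),
    ],
)
def test_season_assignment(date, season):
    assert assign_season(date) == season


def test_season_partition_covers_year():
    days = pd.date_range("2014-01-01", "2014-12-31", freq="D")
    seasons = {s: 0 for s in SEASONS}
    for d in days:
        seasons[assign_season(d)] += 1
    assert sum(seasons.values()) == len(days)
    # three seasons of four months each
    assert seasons["breeding"] == 120 and seasons["parental_care"] == 122


# ---------------------------------------------------------------------------
# vectorized statistics vs scipy


@pytest.mark.parametrize("seed", range(5))
def test_friedman_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 6, size=(12, 3)).astype(float)  # integer -> ties
    chi2, p = friedman_chi2(data[None])
    expected = stats.friedmanchisquare(*data.T)
    assert chi2[0] == pytest.approx(expected.statistic, abs=1e-10)
    assert p[0] == pytest.approx(expected.pvalue, abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_signed_rank_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    d = rng.integers(-4, 5, size=30).astype(float)  # ties and zeros
    if (d == 0).all():
        d[0] = 1.0
    V, p, _ = signed_rank(d[None])
    expected = stats.wilcoxon(d, zero_method="wilcox", correction=False, method="approx")
    assert V[0] == pytest.approx(_vplus(d), abs=1e-10)  # we report V+, scipy the two-sided min
    assert p[0] == pytest.approx(expected.pvalue, abs=1e-10)


def _vplus(d):
    d = d[d != 0]
    r = stats.rankdata(np.abs(d))
    return float(r[d > 0].sum())


def test_signed_rank_symmetry():
    rng = np.random.default_rng(2)
    d = rng.normal(size=25)
    V, p, _ = signed_rank(d[None])
    V2, p2, _ = signed_rank(-d[None])
    n = len(d)
    assert V[0] + V2[0] == pytest.approx(n * (n + 1) / 2)
    assert p[0] == pytest.approx(p2[0])


# ---------------------------------------------------------------------------
# bootstrap battery


def _null_table(n_per_season=40, seed=0, constant=None):
    rng = np.random.default_rng(seed)
    rows = []
    starts = {"breeding": "2014-02-01", "parental_care": "2014-06-01", "nonbreeder": "2014-10-01"}
    for season in SEASONS:
        days = pd.date_range(starts[season], periods=n_per_season, freq="D")
        for d in days:
            val = constant if constant is not None else rng.uniform()
            rows.append({"date": d, "season": season, "prop_resident": val})
    return pd.DataFrame(rows)


def test_bootstrap_friedman_null_identity():
    """Identical values across all days and seasons carry no evidence."""
    table = _null_table(constant=0.4)
    res = bootstrap_friedman(table, "resident", n_boot=1000, seed=1)
    assert res.statistic_mean == pytest.approx(0.0, abs=1e-12)
    assert res.p_mean == pytest.approx(1.0, abs=1e-12)


def test_bootstrap_friedman_deterministic():
    table = _null_table(seed=3)
    a = bootstrap_friedman(table, "resident", n_boot=500, seed=42)
    b = bootstrap_friedman(table, "resident", n_boot=500, seed=42)
    assert a == b


def test_bootstrap_friedman_iteration_convergence():
    """Mean p drifts by < 0.005 between 5k and 10k iterations."""
    table = _null_table(seed=5)
    p5 = bootstrap_friedman(table, "resident", n_boot=5000, seed=1).p_mean
    p10 = bootstrap_friedman(table, "resident", n_boot=10000, seed=2).p_mean
    assert abs(p5 - p10) < 0.005


def test_bootstrap_friedman_detects_shift():
    table = _null_table(seed=7)
    table.loc[table["season"] == "breeding", "prop_resident"] += 0.5
    res = bootstrap_friedman(table, "resident", n_boot=2000, seed=1)
    assert res.p_mean < 0.01
    assert res.significant


def test_bootstrap_friedman_requires_all_seasons():
    table = _null_table().query("season != 'breeding'")
    with pytest.raises(ValueError, match="no observation days"):
        bootstrap_friedman(table, "resident", n_boot=10, seed=0)


def test_bootstrap_wilcoxon_null_and_power():
    table = _null_table(seed=11)
    null_res = bootstrap_wilcoxon_pairs(table, "resident", n_boot=500, seed=3)
    assert len(null_res) == 3
    assert all(r.p_mean > 0.017 for r in null_res)
    shifted = table.copy()
    shifted.loc[shifted["season"] == "breeding", "prop_resident"] += 0.6
    shift_res = bootstrap_wilcoxon_pairs(shifted, "resident", n_boot=500, seed=3)
    flagged = {r.label: r.significant for r in shift_res}
    assert flagged["resident:breeding/parental_care"]
    assert flagged["resident:breeding/nonbreeder"]
    assert not flagged["resident:parental_care/nonbreeder"]


def test_monte_carlo_friedman_constant_blocks():
    values = np.full((10, 3), 2.5)
    res = monte_carlo_friedman(values, n_resamples=200, seed=0)
    assert res.statistic_mean == 0.0
    assert res.p_mean == 1.0


def test_monte_carlo_friedman_matches_exhaustive_enumeration():
    """Four blocks: the permutation p equals exact enumeration over all
    6^4 within-block orderings."""
    values = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
    chi2_obs, _ = friedman_chi2(values[None])
    count = 0
    total = 0
    for perms in itertools.product(itertools.permutations(range(3)), repeat=4):
        arr = np.array([values[i, list(p)] for i, p in enumerate(perms)])
        chi2, _ = friedman_chi2(arr[None])
        total += 1
        if chi2[0] >= chi2_obs[0] - 1e-12:
            count += 1
    p_exact = count / total
    res = monte_carlo_friedman(values, n_resamples=20000, seed=4)
    # MC estimate of a proportion: binomial SE ~ sqrt(p(1-p)/n) < 0.004
    assert res.p_mean == pytest.approx(p_exact, abs=0.015)


def test_monte_carlo_friedman_deterministic():
    rng = np.random.default_rng(9)
    values = rng.normal(size=(8, 3))
    a = monte_carlo_friedman(values, n_resamples=500, seed=5)
    b = monte_carlo_friedman(values, n_resamples=500, seed=5)
    assert a == b


def test_exact_wilcoxon_all_positive_five():
    """Five positive differences: two-sided exact p = 2/32 = 1/16."""
    values = pd.DataFrame(
        {
            "breeding": [1.0, 2.0, 3.0, 4.0, 5.0],
            "parental_care": [0.5, 1.0, 2.0, 3.0, 4.0],
            "nonbreeder": [0.9, 1.8, 2.7, 3.6, 4.5],
        }
    )
    res = {r.label: r for r in exact_wilcoxon_pairs(values)}
    assert res["breeding/parental_care"].p_mean == pytest.approx(1 / 16)
    assert res["breeding/nonbreeder"].p_mean == pytest.approx(1 / 16)


def test_exact_wilcoxon_sign_flip_antisymmetry():
    rng = np.random.default_rng(13)
    base = rng.normal(size=12)
    d = rng.normal(0.3, 1, size=12)
    values = pd.DataFrame(
        {"breeding": base + d, "parental_care": base, "nonbreeder": base - d}
    )
    res = {r.label: r for r in exact_wilcoxon_pairs(values)}
    # flipping all differences mirrors the statistic but not the p-value
    a = res["breeding/parental_care"]
    flipped = pd.DataFrame(
        {"breeding": base, "parental_care": base + d, "nonbreeder": base - d}
    )
    b = {r.label: r for r in exact_wilcoxon_pairs(flipped)}["breeding/parental_care"]
    assert a.p_mean == pytest.approx(b.p_mean)
    n = 12
    assert a.statistic_mean + b.statistic_mean == pytest.approx(n * (n + 1) / 2)


def test_exact_wilcoxon_all_zero_differences():
    values = pd.DataFrame({s: [1.0, 2.0, 3.0] for s in SEASONS})
    res = exact_wilcoxon_pairs(values)
    assert all(r.p_mean == 1.0 for r in res)


def test_subgroup_sizes_by_category_enumeration():
    """{1,2,3} vs {4,5,6}: U statistic of the first group is 0."""
    df = pd.DataFrame(
        {
            "subgroup_size": [1, 2, 3, 4, 5, 6],
            "category": ["resident"] * 3 + ["continuous"] * 3,
        }
    )
    res = subgroup_size_by_category(df)
    pairwise = [r for r in res if r.test == "mann_whitney"]
    assert pairwise[0].label == "resident/continuous"
    assert pairwise[0].statistic_mean == 0.0


def test_subgroup_sizes_identical_groups():
    df = pd.DataFrame(
        {
            "subgroup_size": [1, 2, 3, 9] * 4,
            "category": np.repeat(["resident", "continuous", "periodic", "rare"], 4),
        }
    )
    res = subgroup_size_by_category(df)
    omnibus = res[0]
    assert omnibus.test == "kruskal_wallis"
    assert omnibus.statistic_mean == pytest.approx(0.0, abs=1e-9)
    assert all(r.p_mean > 0.5 for r in res[1:])
    assert len(res) == 1 + 6


def test_kruskal_invariant_under_monotone_transform(rng):
    sizes = rng.integers(1, 12, size=60)
    cats = rng.choice(["resident", "continuous", "periodic", "rare"], size=60)
    df = pd.DataFrame({"subgroup_size": sizes, "category": cats})
    df2 = df.assign(subgroup_size=np.exp(df["subgroup_size"] / 3.0))
    h1 = subgroup_size_by_category(df)[0].statistic_mean
    h2 = subgroup_size_by_category(df2)[0].statistic_mean
    assert h1 == pytest.approx(h2, abs=1e-9)


# ---------------------------------------------------------------------------
# tables from records


def test_season_table_proportions_sum_to_one(small_records):
    from crowflock.presence import assign_categories, feature_table

    feats = feature_table(small_records)
    assignments = assign_categories(feats)
    table = season_table(small_records, assignments)
    props = table[[c for c in table.columns if c.startswith("prop_")]].sum(axis=1)
    assert np.allclose(props, 1.0)
    assert set(table["season"]) <= set(SEASONS)


def test_relative_days_seen_bounds(small_records):
    from crowflock.presence import assign_categories, feature_table

    feats = feature_table(small_records)
    assignments = assign_categories(feats)
    rel = relative_days_seen(small_records, assignments)
    vals = rel[list(SEASONS)].to_numpy()
    assert (vals >= 0).all() and (vals <= 1).all()
    # a bird seen every monitoring day of one season scores 1 there
    assert rel.shape[0] == assignments.shape[0]
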