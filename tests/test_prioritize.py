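"""Rescaling, weighted summation, quantization, coverage fractions, the
coverage-vs-area fitness, and the genetic algorithm."""

import numpy as np
import pandas as pd
import pytest

import oceub as ob


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def one_region(grid):
    return ob.RegionMap(grid, np.ones(grid.n_cells, int), k=1)


def star_inputs(grid, cells_per_species):
    """Fitness inputs for single-cell species on a star tree (one branch per
    species, unit lengths)."""
    species = sorted(cells_per_species)
    all_cells = sorted({c for cc in cells_per_species.values() for c in cc})
    data = pd.DataFrame(False, index=all_cells, columns=species)
    for sp, cc in cells_per_species.items():
        for c in cc:
            data.at[c, sp] = True
    P = ob.PresenceMatrix(data)
    star = ob.set_unit_branch_lengths(ob.parse_newick("(" + ",".join(species) + ");"))
    return ob.build_fitness_inputs(P, star, grid)


# ---------------------------------------------------------------------------
# rescale / weighted sum / quantize
# ---------------------------------------------------------------------------


def test_rescale_simple_region(grid5):
    s = ob.Surface.full(grid5)
    s.values[[0, 1, 2]] = [2.0, 4.0, 6.0]
    labels = np.zeros(grid5.n_cells, int)
    labels[[0, 1, 2]] = 1
    out = ob.rescale_within_regions(s, ob.RegionMap(grid5, labels, k=1))
    assert out.values[[0, 1, 2]].tolist() == [0.0, 0.5, 1.0]
    assert np.isnan(out.values[5])


def test_rescale_constant_region_warns(grid5):
    s = ob.Surface(grid5, np.full(grid5.n_cells, 7.0))
    with pytest.warns(UserWarning, match="constant"):
        out = ob.rescale_within_regions(s, one_region(grid5))
    assert np.all(out.values == 0.0)


def test_rescale_per_region_independent(grid5, rng):
    s = ob.Surface(grid5, rng.uniform(5, 9, grid5.n_cells))
    labels = np.where(np.arange(grid5.n_cells) < grid5.n_cells // 2, 1, 2)
    out = ob.rescale_within_regions(s, ob.RegionMap(grid5, labels, k=2))
    for r in (1, 2):
        v = out.values[labels == r]
        assert v.min() == 0.0 and v.max() == 1.0


def _four(grid, rng):
    return {k: ob.Surface(grid, rng.uniform(0, 1, grid.n_cells)) for k in ("richness", "endemism", "aoe", "pe")}


def test_weighted_sum_single_weight_recovers_surface(grid5, rng):
    surfs = _four(grid5, rng)
    g = ob.Genome(1.0, 0.0, 0.0, 0.0, 0.5)
    out = ob.weighted_sum(surfs, g)
    v = surfs["richness"].values
    expect = (v - v.min()) / (v.max() - v.min())
    np.testing.assert_allclose(out.values, expect)


def test_weighted_sum_equal_surfaces_identity(grid5, rng):
    base = ob.Surface(grid5, rng.uniform(0, 1, grid5.n_cells))
    base.values[0], base.values[1] = 0.0, 1.0  # span the unit interval
    surfs = {k: ob.Surface(grid5, base.values.copy()) for k in ("richness", "endemism", "aoe", "pe")}
    out = ob.weighted_sum(surfs, ob.Genome(0.9, 0.3, 0.7, 0.2, 0.5))
    np.testing.assert_allclose(out.values, base.values, atol=1e-12)


def test_weighted_sum_matches_elementwise_oracle(grid5, rng):
    surfs = _four(grid5, rng)
    g = ob.Genome(0.5, 0.5, 0.5, 0.5, 0.5)
    out = ob.weighted_sum(surfs, g)
    raw = 0.5 * sum(surfs[k].values for k in ("richness", "endemism", "aoe", "pe"))
    expect = (raw - raw.min()) / (raw.max() - raw.min())
    np.testing.assert_allclose(out.values, expect)


def test_weighted_sum_zero_weights_warns(grid5, rng):
    with pytest.warns(UserWarning, match="zero"):
        out = ob.weighted_sum(_four(grid5, rng), ob.Genome(0, 0, 0, 0, 0.5))
    assert np.all(out.values == 0.0)


def test_quantize_extremes_and_monotonicity(grid5, rng):
    s = ob.Surface(grid5, rng.uniform(0, 1, grid5.n_cells))
    s.values[3] = np.nan
    assert ob.quantize(s, 0.0).sum() == grid5.n_cells - 1  # no-data never selected
    assert ob.quantize(s, 1.1).sum() == 0
    sizes = [ob.quantize(s, t).sum() for t in np.linspace(0, 1, 21)]
    assert (np.diff(sizes) <= 0).all()


# ---------------------------------------------------------------------------
# coverage fractions and fitness identity
# ---------------------------------------------------------------------------


def test_coverage_all_and_none(grid5):
    inputs = star_inputs(grid5, {"a": [0], "b": [1], "c": [2]})
    all_sel = np.ones(grid5.n_cells, bool)
    cov = ob.coverage_fractions(all_sel, inputs)
    assert (cov.r, cov.pl, cov.e, cov.pe, cov.area_fraction) == (1.0, 1.0, 1.0, 1.0, 1.0)
    none = ob.coverage_fractions(np.zeros(grid5.n_cells, bool), inputs)
    assert (none.r, none.pl, none.e, none.pe, none.area_fraction) == (0.0, 0.0, 0.0, 0.0, 0.0)


def test_coverage_matches_exhaustive_oracle(grid5):
    # 3 cells, 4 species on a real (non-star) tree
    data = pd.DataFrame(
        [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]], index=[0, 1, 2], columns=list("ABCD")
    ).astype(bool)
    P = ob.PresenceMatrix(data)
    tree = ob.set_unit_branch_lengths(ob.parse_newick("((A,B),(C,D));"))
    inputs = ob.build_fitness_inputs(P, tree, grid5)
    sel = np.zeros(grid5.n_cells, bool)
    sel[0] = True  # captures A and B only
    cov = ob.coverage_fractions(sel, inputs)
    assert cov.r == pytest.approx(2 / 4)
    # captured branches: A, B tips + clade (A,B): length 3 of 6
    assert cov.pl == pytest.approx(3 / 6)
    # WE: A=1 (1 cell), B=1/2, C=1/2, D=1 -> captured 1.5 of 3
    assert cov.e == pytest.approx(1.5 / 3.0)
    # branch endemism weights: tips 1,1/2,1/2,1 ; clades (A,B):1/2,(C,D):1/2
    assert cov.pe == pytest.approx((1 + 0.5 + 0.5) / 4.0)
    assert cov.area_fraction == pytest.approx(1 / grid5.n_cells)


def test_coverage_monotone_under_inclusion(grid5, rng):
    inputs = star_inputs(grid5, {f"s{i}": list(rng.choice(9, rng.integers(1, 4), replace=False)) for i in range(6)})
    sel = np.zeros(grid5.n_cells, bool)
    prev = ob.coverage_fractions(sel, inputs)
    for c in rng.permutation(9):
        sel[c] = True
        cov = ob.coverage_fractions(sel, inputs)
        assert cov.r >= prev.r and cov.pl >= prev.pl and cov.e >= prev.e and cov.pe >= prev.pe
        prev = cov


def test_fitness_result_identity_enforced():
    with pytest.raises(AssertionError):
        ob.FitnessResult(value=0.5, r=1, pl=1, e=1, pe=1, area_fraction=1, selected_cells=np.array([]))


def test_fitness_direct_substitution(grid5):
    # fractions (0.8, 0.8, 0.8, 0.8) at a/A = 0.1 must give 0.7:
    # 10-cell universe, 5 single-cell species, one selected cell holding 4
    data = pd.DataFrame(False, index=[0, 1], columns=list("abcde"))
    data.loc[0, ["a", "b", "c", "d"]] = True
    data.loc[1, "e"] = True
    star = ob.set_unit_branch_lengths(ob.parse_newick("(a,b,c,d,e);"))
    inputs = ob.build_fitness_inputs(ob.PresenceMatrix(data), star, grid5, total_cells=10)
    sel = np.zeros(grid5.n_cells, bool)
    sel[0] = True  # 1 of the 10 accounted cells = 0.1 of the area
    cov = ob.coverage_fractions(sel, inputs)
    assert (cov.r, cov.pl, cov.e, cov.pe) == (0.8, 0.8, 0.8, 0.8)
    assert cov.area_fraction == pytest.approx(0.1)
    value = (cov.r + cov.pl + cov.e + cov.pe) / 4 - cov.area_fraction
    assert value == pytest.approx(0.7)


def test_fitness_select_all_scores_zero(grid5, rng):
    surfs = _four(grid5, rng)
    inputs = star_inputs(grid5, {"a": [0], "b": [5], "c": [11]})
    res = ob.fitness(ob.Genome(0.5, 0.5, 0.5, 0.5, 0.0), surfs, one_region(grid5), inputs)
    assert res.value == pytest.approx(0.0)
    assert res.area_fraction == 1.0


def test_fitness_bounded_on_random_genomes(grid5, rng):
    surfs = _four(grid5, rng)
    inputs = star_inputs(grid5, {f"s{i}": list(rng.choice(20, rng.integers(1, 5), replace=False)) for i in range(8)})
    ev = ob.FitnessEvaluator(surfs, one_region(grid5), inputs)
    for _ in range(200):
        v = ev(ob.Genome.from_array(rng.uniform(0, 1, 5)))
        assert -1.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


def concave(genome):
    return 1.0 - float(((genome.as_array() - 0.3) ** 2).sum())


def test_ga_recovers_known_optimum():
    res = ob.ga_optimize(concave, ob.GAConfig(seed=5))
    assert np.all(np.abs(res.best_genome.as_array() - 0.3) < 0.05)
    assert res.n_generations <= 100


def test_ga_history_nondecreasing_and_reproducible():
    r1 = ob.ga_optimize(concave, ob.GAConfig(seed=9))
    r2 = ob.ga_optimize(concave, ob.GAConfig(seed=9))
    assert (r1.history["best"].diff().dropna() >= 0).all()
    pd.testing.assert_frame_equal(r1.history, r2.history)
    assert r1.best_genome == r2.best_genome


def test_ga_pure_elitism_returns_best_of_initial_population():
    cfg = ob.GAConfig(
        pop_size=10, elite_fraction=1.0, random_pick_fraction=0.0,
        crossover_rate=0.0, mutation_rate=0.0, stall_generations=3, seed=4,
    )
    res = ob.ga_optimize(concave, cfg)
    rng = np.random.default_rng(4)
    pop = rng.uniform(0, 1, (10, 5))
    pop[0] = 0.5
    expect = max(concave(ob.Genome.from_array(g)) for g in pop)
    assert res.best_fitness == pytest.approx(expect)


def test_ga_rejects_tiny_population():
    with pytest.raises(ValueError):
        ob.GAConfig(pop_size=1)


def test_genome_bounds_enforced():
    with pytest.raises(ValueError):
        ob.Genome(1.2, 0, 0, 0, 0)
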