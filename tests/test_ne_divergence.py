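"""Recombination-distance bins, the LD → Ne chain, and divergence times."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import popdrift as pk

from conftest import build_panel


# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------

def test_default_grid_has_246_bins_with_stated_bounds():
    bins = pk.make_bins()
    assert len(bins) == 246
    assert bins.iloc[0]["start_cM"] == pytest.approx(0.005)
    assert bins.iloc[0]["end_cM"] == pytest.approx(0.010)
    assert bins.iloc[-1]["start_cM"] == pytest.approx(0.250)
    # representative distance is the midpoint in Morgans
    assert bins.iloc[0]["c_M"] == pytest.approx(0.0075 / 100)


def test_width_equal_step_gives_disjoint_partition():
    bins = pk.make_bins(0.01, 0.05, step_cm=0.01, width_cm=0.01)
    starts = bins["start_cM"].to_numpy()
    ends = bins["end_cM"].to_numpy()
    np.testing.assert_allclose(ends[:-1], starts[1:])


def test_pair_distance_membership_in_overlapping_bins():
    bins = pk.make_bins()
    d = 0.0075
    containing = bins[(bins["start_cM"] <= d) & (d < bins["end_cM"])]
    np.testing.assert_allclose(containing["start_cM"], [0.005, 0.006, 0.007])


# ---------------------------------------------------------------------------
# r2 by distance
# ---------------------------------------------------------------------------

def test_perfectly_correlated_close_pair_fills_containing_bins():
    rng = np.random.default_rng(0)
    col = rng.binomial(2, 0.5, 40).astype(np.int8)
    calls = np.stack([col, col], axis=1)
    panel = build_panel(calls, pos_cm=[0.1000, 0.1082])  # 0.0082 cM apart
    binned = pk.r2_by_distance(panel, "pop1", pk.make_bins())
    hit = binned.n_pairs > 0
    np.testing.assert_allclose(binned.bins["start_cM"][hit],
                               [0.005, 0.006, 0.007, 0.008])
    np.testing.assert_allclose(binned.mean_r2[hit], 1.0)


def test_distant_snps_produce_no_pairs():
    rng = np.random.default_rng(1)
    calls = rng.binomial(2, 0.5, size=(30, 4)).astype(np.int8)
    panel = build_panel(calls, pos_cm=[0.0, 10.0, 20.0, 30.0])
    binned = pk.r2_by_distance(panel, "pop1", pk.make_bins())
    assert binned.n_pairs.sum() == 0
    assert len(pk.ne_trajectory(binned)) == 0


def test_bin_means_match_exhaustive_pair_enumeration():
    rng = np.random.default_rng(2)
    calls = rng.binomial(2, rng.uniform(0.3, 0.7, 4), size=(60, 4)).astype(np.int8)
    # distances chosen strictly inside bins so float edge cases cannot
    # make the oracle and the binned accumulation disagree on membership
    pos_cm = [0.0, 0.00634, 0.01153, 0.24427]
    panel = build_panel(calls, pos_cm=pos_cm)
    bins = pk.make_bins()
    binned = pk.r2_by_distance(panel, "pop1", bins)
    # brute force: every pair, every bin
    n_pairs = np.zeros(len(bins))
    sum_r2 = np.zeros(len(bins))
    for i in range(4):
        for j in range(i + 1, 4):
            d = abs(pos_cm[j] - pos_cm[i])
            r2 = pk.genotype_r2(panel, i, j)
            for b, row in bins.iterrows():
                if row["start_cM"] <= d < row["end_cM"]:
                    n_pairs[b] += 1
                    sum_r2[b] += r2
    np.testing.assert_array_equal(binned.n_pairs, n_pairs)
    np.testing.assert_allclose(binned.sum_r2, sum_r2, atol=1e-12)


# ---------------------------------------------------------------------------
# adjust, ne_point, trajectory
# ---------------------------------------------------------------------------

def test_adjustment_vanishes_for_large_samples():
    assert pk.adjust_r2(0.05, 10**9) == pytest.approx(0.05, rel=1e-6)
    assert pk.adjust_r2(0.05, 100) == pytest.approx(0.04)
    assert np.isnan(pk.adjust_r2(0.005, 100))  # below noise floor -> excluded


def test_ne_point_closed_form_and_monotonicity():
    assert pk.ne_point(0.001, 0.5) == 0.0
    assert pk.ne_point(0.001, 0.05) == pytest.approx(4500.0)
    values = [pk.ne_point(0.001, r2) for r2 in np.linspace(0.01, 0.5, 50)]
    assert all(a > b for a, b in zip(values, values[1:]))


def _toy_binned(r2_values, n_pairs=40, n_samples=100, n_blocks=4):
    """BinnedLD with uniform per-block composition for deterministic checks."""
    bins = pk.make_bins(0.05, 0.25, step_cm=0.05, width_cm=0.05)
    k = len(bins)
    r2 = np.broadcast_to(np.asarray(r2_values, float), (k,)).copy()
    n = np.full(k, n_pairs)
    nb = np.full((k, n_blocks), n_pairs // n_blocks)
    sb = nb * r2[:, None]
    return pk.BinnedLD(bins, n, r2 * n, nb, sb, population="toy",
                       n_samples=n_samples)


def test_trajectory_time_axis_is_inverse_of_distance():
    binned = _toy_binned(0.2)
    traj = pk.ne_trajectory(binned)
    # bin at midpoint 0.075 cM = 0.00075 M -> t = 1/(2c)
    row = traj[traj["start_cM"] == 0.05].iloc[0]
    assert row["t_generations"] == pytest.approx(1.0 / (2 * 0.00075))
    assert np.all(np.diff(traj["t_generations"]) < 0)  # later bins = more recent


def test_time_point_closed_form():
    binned = _toy_binned(0.2)
    traj = pk.ne_trajectory(binned)
    np.testing.assert_allclose(traj["t_generations"],
                               1.0 / (2.0 * traj["c_M"]))
    assert pytest.approx(1000.0) == 1.0 / (2 * 0.0005)  # 0.05 cM -> 1000 gens


def test_identical_pair_values_give_zero_width_ci():
    binned = _toy_binned(0.2)
    traj = pk.ne_trajectory(binned)
    np.testing.assert_allclose(traj["ci_low"], traj["ne"], rtol=1e-9)
    np.testing.assert_allclose(traj["ci_high"], traj["ne"], rtol=1e-9)


def test_ci_contains_point_estimate(wf_binned):
    traj = pk.ne_trajectory(wf_binned)
    ok = np.isfinite(traj["ci_low"])
    assert ((traj["ci_low"][ok] <= traj["ne"][ok] + 1e-9)
            & (traj["ne"][ok] <= traj["ci_high"][ok] + 1e-9)).all()


def test_excluding_bins_leaves_other_bins_unchanged(wf_binned):
    traj = pk.ne_trajectory(wf_binned)
    sub = pk.BinnedLD(wf_binned.bins[50:].reset_index(drop=True),
                      wf_binned.n_pairs[50:], wf_binned.sum_r2[50:],
                      wf_binned.n_pairs_block[50:], wf_binned.sum_r2_block[50:],
                      population=wf_binned.population,
                      n_samples=wf_binned.n_samples)
    traj_sub = pk.ne_trajectory(sub)
    merged = traj.merge(traj_sub, on="start_cM", suffixes=("", "_sub"))
    np.testing.assert_allclose(merged["ne"], merged["ne_sub"], rtol=1e-12)


# ---------------------------------------------------------------------------
# long-term Ne
# ---------------------------------------------------------------------------

def test_long_term_ne_of_constant_trajectory():
    # choose per-bin r2 so every bin maps to exactly Ne = 500
    bins = pk.make_bins(0.05, 0.25, step_cm=0.05, width_cm=0.05)
    r2 = 1.0 / (2.0 + 4.0 * bins["c_M"].to_numpy() * 500.0) + 0.01  # n = 100
    binned = _toy_binned(r2)
    traj = pk.ne_trajectory(binned)
    np.testing.assert_allclose(traj["ne"], 500.0, rtol=1e-9)
    lt = pk.long_term_ne(binned)
    assert lt.ne_harmonic == pytest.approx(500.0, rel=1e-9)


def test_harmonic_mean_arithmetic():
    vals = np.array([4000.0, 6000.0])
    hm = 2.0 / (1.0 / vals).sum()
    assert hm == pytest.approx(4800.0)
    traj = pd.DataFrame({"ne": vals})
    assert hm <= vals.mean()


def test_long_term_ne_is_at_most_arithmetic_mean(wf_binned):
    lt = pk.long_term_ne(wf_binned)
    traj = pk.ne_trajectory(wf_binned)
    pos = traj["ne"][traj["ne"] > 0]
    assert lt.ne_harmonic <= pos.mean() + 1e-9
    assert lt.ci_low <= lt.ne_harmonic <= lt.ci_high


def test_ne_chain_on_independent_coalescent_simulator():
    """Coalescent (msprime) data of known N=100 through the same LD → Ne chain.

    An independent simulator cross-checks the whole estimator path. The
    Sved-style inversion on a common-variant (MAF ≥ 0.05) panel carries an
    inherent upward bias of roughly 2x at equilibrium, so the assertion is
    an order-of-magnitude recovery, not the generator-calibrated band.
    """
    import msprime

    frames, gts = [], []
    for c in range(10):  # 10 independent 5-Mb chromosomes at 1 cM/Mb
        ts = msprime.sim_ancestry(samples=100, population_size=100,
                                  sequence_length=5e6,
                                  recombination_rate=1e-8,
                                  random_seed=101 + c)
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=101 + c)
        geno = ts.genotype_matrix()
        gt = np.minimum((geno[:, 0::2] + geno[:, 1::2]).T, 2).astype(np.int8)
        pos_cm = np.array([s.position for s in ts.sites()]) * 1e-8 * 100
        f = gt.mean(axis=0) / 2
        keep = np.minimum(f, 1 - f) >= 0.05
        frames.append(pd.DataFrame({
            "chrom": str(c + 1),
            "pos_bp": (pos_cm[keep] * 1e6).astype(np.int64) + 1,
            "id": [f"c{c}m{i}" for i in range(int(keep.sum()))],
            "ref_allele": "A", "alt_allele": "G", "pos_cM": pos_cm[keep],
        }))
        gts.append(gt[:, keep])
    samples = pd.DataFrame({"id": [f"s{i}" for i in range(100)],
                            "population": "pop1", "group_tags": ""})
    panel = pk.GenotypePanel(pd.concat(frames, ignore_index=True), samples,
                             np.hstack(gts))
    binned = pk.r2_by_distance(panel, "pop1", pk.make_bins())
    estimate = pk.recent_ne(pk.ne_trajectory(binned))
    assert 100 / 3 <= estimate <= 100 * 3


# ---------------------------------------------------------------------------
# divergence time
# ---------------------------------------------------------------------------

def test_divergence_zero_fst_is_zero_time():
    res = pk.divergence_time(0.0, 5000.0)
    assert res.t_generations == 0.0
    assert res.t_years == 0.0


def test_divergence_closed_form_high_precision():
    res = pk.divergence_time(0.1, 5000.0)
    expected = np.log(0.9) / np.log(1 - 1 / 10000)
    assert res.t_generations == pytest.approx(expected, rel=1e-12)
    assert res.t_generations == pytest.approx(1053.55, abs=0.01)
    assert res.t_years == pytest.approx(expected * 25, rel=1e-12)


def test_divergence_pair_ne_is_harmonic_mean():
    a = pk.LongTermNe("A", 4000.0, np.nan, np.nan, 10)
    b = pk.LongTermNe("B", 6000.0, np.nan, np.nan, 10)
    res = pk.divergence_time(0.05, a, b)
    assert res.ne_pair == pytest.approx(4800.0)
    assert res.pop_a == "A" and res.pop_b == "B"


def test_divergence_rejects_fst_at_or_above_one():
    with pytest.raises(ValueError):
        pk.divergence_time(1.0, 5000.0)


def test_negative_fst_clipped_to_zero():
    assert pk.divergence_time(-0.003, 5000.0).t_generations == 0.0


@given(st.floats(0.001, 0.9), st.floats(50, 1e6))
def test_divergence_inverts_exactly(fst, ne):
    t = pk.divergence_time(fst, ne).t_generations
    assert pk.fst_from_divergence(t, ne) == pytest.approx(fst, rel=1e-9)


@given(st.floats(0.01, 0.8), st.floats(100, 1e5))
def test_divergence_monotone_in_fst_and_ne(fst, ne):
    t = pk.divergence_time(fst, ne).t_generations
    assert pk.divergence_time(fst + 0.05, ne).t_generations > t
    assert pk.divergence_time(fst, ne * 2).t_generations > t


# ---------------------------------------------------------------------------
# divergence matrix
# ---------------------------------------------------------------------------

def test_duplicated_population_label_has_near_zero_divergence(wf_run):
    panel, _ = wf_run
    samples = panel.samples.copy()
    half = panel.n_samples // 2
    samples.loc[:half - 1, "population"] = "X"
    samples.loc[half:, "population"] = "Y"
    split = pk.GenotypePanel(panel.variants, samples, panel.calls)
    mat, pairs, ne_table = pk.divergence_matrix(split, ["X", "Y"])
    np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
    np.testing.assert_allclose(np.diag(mat.to_numpy()), 0.0)
    # same underlying population under two names: a few generations at most
    assert mat.loc["X", "Y"] < 50.0
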