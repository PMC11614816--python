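"""LD-decay effective population size and FST-based divergence times.

The chain of inference runs:

1. Bin intra-chromosomal SNP pairs into overlapping recombination-distance
   categories (default: starts every 0.001 cM from 0.005 to 0.25 cM, each
   bin 0.005 cM wide) and average genotype r² per bin.
2. Correct each bin mean for finite sample size (r² − 1/n) and map it to an
   effective size with Ne ≈ (1/r² − 2) / (4c), where c is the bin midpoint
   in Morgans. A bin at distance c reflects drift about t = 1/(2c)
   generations ago, so the bins trace an Ne trajectory through time.
3. Summarize the trajectory by its harmonic mean — the long-term Ne that
   governs cumulative drift.
4. Convert pairwise FST between two populations into a divergence time via
   T = ln(1 − FST) / ln(1 − 1/(2·Ne)) generations (25 years per generation
   by default), using the harmonic mean of the two populations' long-term
   Ne as the pair Ne.

Confidence intervals propagate a delete-one-block jackknife (20 contiguous
genomic blocks of SNP pairs) through the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fstats import fst_matrix, jackknife_se_from_loo
from .panelio import MISSING, GenotypePanel

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class LongTermNe:
    population: str
    ne_harmonic: float
    ci_low: float
    ci_high: float
    n_points: int
    n_excluded: int = 0


@dataclass(frozen=True)
class DivergenceResult:
    pop_a: str
    pop_b: str
    fst: float
    ne_pair: float
    t_generations: float
    t_years: float
    generation_years: float


@dataclass
class BinnedLD:
    """Per-bin pair counts and r² sums, with per-block splits for jackknife."""

    bins: pd.DataFrame          # start_cM, end_cM, c_M
    n_pairs: np.ndarray         # (n_bins,)
    sum_r2: np.ndarray          # (n_bins,)
    n_pairs_block: np.ndarray   # (n_bins, n_blocks)
    sum_r2_block: np.ndarray    # (n_bins, n_blocks)
    population: str = ""
    n_samples: int = 0

    @property
    def mean_r2(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_pairs > 0, self.sum_r2 / self.n_pairs, np.nan)


def make_bins(start_cm: float = 0.005, stop_cm: float = 0.25,
              step_cm: float = 0.001, width_cm: float = 0.005) -> pd.DataFrame:
    """Overlapping recombination-distance bins [s, s+width) on a regular grid.

    Bin starts run from ``start_cm`` to ``stop_cm`` inclusive in steps of
    ``step_cm``; consecutive bins overlap whenever ``width_cm > step_cm``.
    ``c_M`` is the bin midpoint converted to Morgans.
    """
    if not start_cm < stop_cm:
        raise ValueError("start_cm must be < stop_cm")
    if width_cm <= 0 or step_cm <= 0:
        raise ValueError("step_cm and width_cm must be positive")
    n = int(round((stop_cm - start_cm) / step_cm)) + 1
    starts = np.round(start_cm + step_cm * np.arange(n), 10)
    return pd.DataFrame({
        "start_cM": starts,
        "end_cM": np.round(starts + width_cm, 10),
        "c_M": (starts + width_cm / 2.0) / 100.0,
    })


def _standardized_calls(calls: np.ndarray):
    """Columns standardized over non-missing entries, 0 where missing."""
    obs = calls != MISSING
    x = calls.astype(float)
    x[~obs] = np.nan
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    return x, obs, mu, sd


def r2_by_distance(panel: GenotypePanel, population: str, bins: pd.DataFrame,
                   n_blocks: int = 20) -> BinnedLD:
    """Average genotype r² of intra-chromosomal SNP pairs per distance bin.

    Every pair whose cM separation falls inside a bin contributes its r² to
    that bin; with overlapping bins a pair contributes to all bins
    containing it. Pairs are also tallied into ``n_blocks`` contiguous
    genomic blocks (keyed by the left SNP) for jackknife CIs. Requires
    pos_cM annotation.
    """
    cm_all = panel.variants["pos_cM"].to_numpy(dtype=float)
    if not np.isfinite(cm_all).all():
        raise ValueError("panel must be annotated with genetic positions (pos_cM)")
    idx = panel.sample_indices(population)
    n_samples = idx.size
    starts = bins["start_cM"].to_numpy()
    width = float(bins["end_cM"].iloc[0] - bins["start_cM"].iloc[0])
    max_offsets = int(np.ceil(width / min(np.diff(starts)))) if len(starts) > 1 else 1
    d_min, d_max = float(starts[0]), float(bins["end_cM"].to_numpy()[-1])

    n_bins = len(bins)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    sum_r2 = np.zeros(n_bins)
    n_pairs_b = np.zeros((n_bins, n_blocks), dtype=np.int64)
    sum_r2_b = np.zeros((n_bins, n_blocks))

    # contiguous genomic blocks over the variant order
    block_of = np.minimum(
        np.arange(panel.n_variants) * n_blocks // max(panel.n_variants, 1),
        n_blocks - 1,
    )
    chroms = panel.variants["chrom"].astype(str).to_numpy()

    for chrom in dict.fromkeys(chroms):
        vidx = np.flatnonzero(chroms == chrom)
        cm = cm_all[vidx]
        order = np.argsort(cm, kind="stable")
        vidx, cm = vidx[order], cm[order]
        calls = panel.calls[np.ix_(idx, vidx)]
        x, obs, mu, sd = _standardized_calls(calls)
        has_missing = not obs.all()
        hi = np.searchsorted(cm, cm + d_max, side="left")
        for i in range(len(vidx)):
            lo = np.searchsorted(cm, cm[i] + d_min, side="left")
            if lo >= hi[i]:
                continue
            js = np.arange(lo, hi[i])
            d = cm[js] - cm[i]
            if has_missing:
                both = obs[:, [i]] & obs[:, js]
                cnt = both.sum(axis=0)
                xi = np.where(both, np.nan_to_num(x[:, [i]]), np.nan)
                xj = np.where(both, x[:, js], np.nan)
                with np.errstate(invalid="ignore", divide="ignore"):
                    mi = np.nansum(xi, axis=0) / cnt
                    mj = np.nansum(xj, axis=0) / cnt
                    cov = np.nansum((xi - mi) * (xj - mj), axis=0) / cnt
                    vi = np.nansum((xi - mi) ** 2, axis=0) / cnt
                    vj = np.nansum((xj - mj) ** 2, axis=0) / cnt
                    r2 = cov**2 / (vi * vj)
                ok = (cnt >= 2) & np.isfinite(r2)
            else:
                xi = x[:, i]
                if sd[i] == 0:
                    continue
                with np.errstate(invalid="ignore", divide="ignore"):
                    cov = ((xi - mu[i])[:, None] * (x[:, js] - mu[js])).mean(axis=0)
                    r2 = cov**2 / (sd[i] ** 2 * sd[js] ** 2)
                ok = np.isfinite(r2)
            if not ok.any():
                continue
            js_ok, d_ok, r2_ok = js[ok], d[ok], r2[ok]
            # bins containing d: starts in (d - width, d]
            i_hi = np.searchsorted(starts, d_ok, side="right") - 1
            i_lo = np.searchsorted(starts, d_ok - width, side="right")
            blk = block_of[vidx[i]]
            for off in range(max_offsets):
                b = i_lo + off
                sel = b <= i_hi
                if not sel.any():
                    break
                bsel = b[sel]
                np.add.at(n_pairs, bsel, 1)
                np.add.at(sum_r2, bsel, r2_ok[sel])
                np.add.at(n_pairs_b[:, blk], bsel, 1)
                np.add.at(sum_r2_b[:, blk], bsel, r2_ok[sel])

    return BinnedLD(bins.copy(), n_pairs, sum_r2, n_pairs_b, sum_r2_b,
                    population=population, n_samples=n_samples)


def adjust_r2(mean_r2, n_samples: int, correct: bool = True):
    """Finite-sample correction: adjusted r² = r² − 1/n.

    Adjusted values ≤ 0 are indistinguishable from sampling noise and are
    returned as NaN (the bin is excluded). ``correct=False`` passes the raw
    mean through (the literal-formula mode).
    """
    mean_r2 = np.asarray(mean_r2, dtype=float)
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    adj = mean_r2 - (1.0 / n_samples if correct else 0.0)
    return np.where(adj > 0, adj, np.nan)


def ne_point(c_morgans: float, r2: float) -> float:
    """Ne ≈ (1/r² − 2) / (4c); negative results (r² > 0.5) report as 0."""
    if not c_morgans > 0:
        raise ValueError("c must be positive (Morgans)")
    if not r2 > 0:
        return float("nan")
    ne = (1.0 / r2 - 2.0) / (4.0 * c_morgans)
    return max(ne, 0.0)


_ne_point_vec = np.vectorize(ne_point, otypes=[float])


def ne_trajectory(binned: BinnedLD, correct: bool = True,
                  min_pairs: int = 1) -> pd.DataFrame:
    """Per-bin Ne through time with 95% jackknife confidence intervals.

    Each bin at midpoint c Morgans yields a point at t = 1/(2c) generations
    with Ne from the adjusted bin mean; the CI propagates a delete-one-block
    jackknife over SNP pairs through the correction and the Ne formula.
    Bins without pairs or with non-positive adjusted r² are dropped.
    """
    n = binned.n_samples
    c = binned.bins["c_M"].to_numpy()
    mean_r2 = binned.mean_r2
    adj = adjust_r2(mean_r2, n, correct=correct)
    valid = (binned.n_pairs >= min_pairs) & np.isfinite(adj)
    ne = np.full(len(c), np.nan)
    ne[valid] = _ne_point_vec(c[valid], adj[valid])

    ci_low = np.full(len(c), np.nan)
    ci_high = np.full(len(c), np.nan)
    g = binned.n_pairs_block.shape[1]
    for b in np.flatnonzero(valid):
        cnt_loo = binned.n_pairs[b] - binned.n_pairs_block[b]
        sum_loo = binned.sum_r2[b] - binned.sum_r2_block[b]
        used = binned.n_pairs_block[b] > 0
        if used.sum() < 2 or (cnt_loo[used] == 0).any():
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            adj_loo = adjust_r2(sum_loo[used] / cnt_loo[used], n, correct=correct)
        if not np.isfinite(adj_loo).all():
            continue
        ne_loo = _ne_point_vec(c[b], adj_loo)
        se = jackknife_se_from_loo(ne[b], ne_loo, binned.n_pairs_block[b][used])
        if np.isfinite(se):
            ci_low[b] = max(ne[b] - Z95 * se, 0.0)
            ci_high[b] = ne[b] + Z95 * se

    out = pd.DataFrame({
        "start_cM": binned.bins["start_cM"],
        "c_M": c,
        "t_generations": 1.0 / (2.0 * c),
        "mean_r2": mean_r2,
        "adjusted_r2": adj,
        "ne": ne,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "n_pairs": binned.n_pairs,
    })
    return out[valid].reset_index(drop=True)


def recent_ne(trajectory: pd.DataFrame, min_start_cm: float = 0.2) -> float:
    """Mean Ne over the largest-distance bins (the most recent time points).

    The bins at the top of the distance grid (start ≥ ``min_start_cm``)
    probe t = 1/(2c) ≈ 200–250 generations ago and are the best-populated
    part of the trajectory; their average is the natural point estimate of
    recent Ne.
    """
    recent = trajectory[trajectory["start_cM"] >= min_start_cm]
    if recent.empty:
        raise ValueError("no trajectory points at the requested distances")
    return float(recent["ne"].mean())


def _harmonic_mean(values: np.ndarray) -> float:
    return values.size / (1.0 / values).sum()


def long_term_ne(binned: BinnedLD, correct: bool = True,
                 min_pairs: int = 1) -> LongTermNe:
    """Harmonic-mean Ne over the trajectory, with a jackknife 95% CI.

    Points with Ne ≤ 0 are excluded from the mean and counted. The CI
    re-derives the whole trajectory with each genomic block of SNP pairs
    deleted in turn.
    """
    traj = ne_trajectory(binned, correct=correct, min_pairs=min_pairs)
    ne_vals = traj["ne"].to_numpy()
    pos = ne_vals > 0
    n_excluded = int((~pos).sum())
    if not pos.any():
        raise ValueError(f"no positive Ne points for {binned.population!r}")
    est = _harmonic_mean(ne_vals[pos])

    n = binned.n_samples
    c = binned.bins["c_M"].to_numpy()
    g = binned.n_pairs_block.shape[1]
    loo_means, loo_weights = [], []
    for j in range(g):
        cnt = binned.n_pairs - binned.n_pairs_block[:, j]
        ssum = binned.sum_r2 - binned.sum_r2_block[:, j]
        if binned.n_pairs_block[:, j].sum() == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_loo = np.where(cnt >= min_pairs, ssum / np.where(cnt > 0, cnt, 1), np.nan)
            adj_loo = adjust_r2(mean_loo, n, correct=correct)
        ok = np.isfinite(adj_loo)
        if not ok.any():
            continue
        ne_loo = _ne_point_vec(c[ok], adj_loo[ok])
        ne_loo = ne_loo[ne_loo > 0]
        if ne_loo.size == 0:
            continue
        loo_means.append(_harmonic_mean(ne_loo))
        loo_weights.append(binned.n_pairs_block[:, j].sum())
    if len(loo_means) >= 2:
        se = jackknife_se_from_loo(est, np.array(loo_means), np.array(loo_weights))
        lo, hi = max(est - Z95 * se, 0.0), est + Z95 * se
    else:
        lo = hi = float("nan")
    return LongTermNe(binned.population, float(est), float(lo), float(hi),
                      int(pos.sum()), n_excluded)


# ---------------------------------------------------------------------------
# Divergence times
# ---------------------------------------------------------------------------

def divergence_time(fst: float, ne_a, ne_b=None,
                    generation_years: float = 25.0) -> DivergenceResult:
    """T = ln(1 − FST) / ln(1 − 1/(2·Ne)) generations between two populations.

    ``ne_a``/``ne_b`` may be floats or :class:`LongTermNe`; with two values
    the pair Ne is their harmonic mean. Negative FST (estimator noise) is
    clipped to 0; FST ≥ 1 is an error (infinite divergence).
    """
    def _ne(x):
        return x.ne_harmonic if isinstance(x, LongTermNe) else float(x)

    names = (
        ne_a.population if isinstance(ne_a, LongTermNe) else "popA",
        ne_b.population if isinstance(ne_b, LongTermNe) else "popB",
    )
    na = _ne(ne_a)
    ne_pair = na if ne_b is None else _harmonic_mean(np.array([na, _ne(ne_b)]))
    if not ne_pair > 0.5:
        raise ValueError("pair Ne must exceed 0.5")
    fst = max(float(fst), 0.0)
    if fst >= 1.0:
        raise ValueError("FST >= 1 implies infinite divergence")
    t = np.log1p(-fst) / np.log1p(-1.0 / (2.0 * ne_pair))
    return DivergenceResult(names[0], names[1], fst, float(ne_pair),
                            float(t), float(t * generation_years),
                            generation_years)


def fst_from_divergence(t_generations: float, ne: float) -> float:
    """Inverse relation FST = 1 − (1 − 1/(2Ne))^T (pure drift after a split)."""
    return float(-np.expm1(t_generations * np.log1p(-1.0 / (2.0 * ne))))


def divergence_matrix(panel: GenotypePanel, populations=None,
                      estimator: str = "wc", bins: pd.DataFrame = None,
                      generation_years: float = 25.0, correct_r2: bool = True,
                      n_blocks: int = 20) -> tuple:
    """Pairwise divergence times for all populations in a panel.

    Computes each population's LD-based long-term Ne, the pairwise FST
    matrix, and the divergence time for every unordered pair. Returns
    ``(matrix_generations, pairs_table, ne_table)`` with a symmetric
    zero-diagonal matrix in generations.
    """
    pops = list(populations) if populations is not None else panel.populations
    if bins is None:
        bins = make_bins()
    ne_of = {}
    for pop in pops:
        binned = r2_by_distance(panel, pop, bins, n_blocks=n_blocks)
        ne_of[pop] = long_term_ne(binned, correct=correct_r2)
    fst = fst_matrix(panel, pops, estimator=estimator)
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            res = divergence_time(fst.loc[a, b], ne_of[a], ne_of[b],
                                  generation_years=generation_years)
            mat.loc[a, b] = mat.loc[b, a] = res.t_generations
            rows.append(res)
    pairs = pd.DataFrame([r.__dict__ for r in rows])
    ne_table = pd.DataFrame([n.__dict__ for n in ne_of.values()])
    return mat, pairs, ne_table
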