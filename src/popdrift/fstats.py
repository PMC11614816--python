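"""Pairwise FST and outgroup f3-statistics with weighted block jackknife.

FST is computed as a ratio of averages (sum of per-site numerators over sum
of per-site denominators), never an average of per-site ratios. Two
estimators are provided: Weir & Cockerham's 1984 variance-components
estimator (default) and the Hudson estimator in the ratio-of-averages form.

The outgroup f3-statistic f3(O; A, B) is the mean over variants of
(o − a)(o − b) on population allele frequencies — the shared-drift form
used for ranking, without the finite-sample heterozygosity correction
(available via a flag). Standard errors come from a weighted delete-one
block jackknife with blocks cut by genetic position (5 cM default) or into
equal-count chunks when no genetic map is attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panelio import MISSING, GenotypePanel


@dataclass(frozen=True)
class FstResult:
    pop_a: str
    pop_b: str
    fst: float          # unclipped ratio-of-averages estimate
    fst_clipped: float  # max(fst, 0), for divergence-time use
    n_sites: int
    estimator: str


@dataclass(frozen=True)
class F3Result:
    outgroup: str
    pop_a: str
    pop_b: str
    f3: float
    se: float
    z: float
    n_sites: int
    n_blocks: int


def _pop_site_stats(panel: GenotypePanel, pop: str):
    """Per-variant (frequency, diploid count, observed-het proportion)."""
    idx = panel.sample_indices(pop)
    calls = panel.calls[idx]
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n)
        h = ((calls == 1) & obs).sum(axis=0) / n
    p[n == 0] = np.nan
    h[n == 0] = np.nan
    return p, n, h


def _hudson_components(p1, n1_alleles, p2, n2_alleles):
    """Per-site Hudson numerator/denominator (sample counts in alleles)."""
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1_alleles - 1)
           - p2 * (1 - p2) / (n2_alleles - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _wc_components(p1, n1, h1, p2, n2, h2):
    """Weir–Cockerham (1984) per-site a, b, c for two populations.

    ``n`` are diploid sample counts, ``h`` observed heterozygote proportions.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(panel: GenotypePanel, pop_a: str, pop_b: str,
                 estimator: str = "wc") -> FstResult:
    """Ratio-of-averages FST between two populations.

    Sites need ≥2 non-missing samples in each population and must be
    polymorphic across the pooled pair; everything else is excluded.
    """
    if estimator not in {"wc", "hudson"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    p1, n1, h1 = _pop_site_stats(panel, pop_a)
    p2, n2, h2 = _pop_site_stats(panel, pop_b)
    pooled = (2 * n1 * p1 + 2 * n2 * p2) / (2 * n1 + 2 * n2)
    use = (n1 >= 2) & (n2 >= 2) & (pooled > 0) & (pooled < 1)
    use &= np.isfinite(p1) & np.isfinite(p2)
    if not use.any():
        raise ValueError(f"no usable sites for ({pop_a}, {pop_b})")
    if estimator == "hudson":
        num, den = _hudson_components(p1[use], 2 * n1[use], p2[use], 2 * n2[use])
        fst = float(num.sum() / den.sum())
    else:
        a, b, c = _wc_components(p1[use], n1[use], h1[use], p2[use], n2[use], h2[use])
        fst = float(a.sum() / (a + b + c).sum())
    return FstResult(pop_a, pop_b, fst, max(fst, 0.0), int(use.sum()), estimator)


def fst_matrix(panel: GenotypePanel, populations=None,
               estimator: str = "wc") -> pd.DataFrame:
    """Symmetric matrix of clipped pairwise FST over populations."""
    pops = list(populations) if populations is not None else panel.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            res = pairwise_fst(panel, a, b, estimator=estimator)
            mat.loc[a, b] = mat.loc[b, a] = res.fst_clipped
    return mat


# ---------------------------------------------------------------------------
# f3 and the block jackknife
# ---------------------------------------------------------------------------

def outgroup_f3(freq_o, freq_a, freq_b) -> np.ndarray:
    """Per-variant shared-drift values (o − a)(o − b)."""
    freq_o = np.asarray(freq_o, dtype=float)
    return (freq_o - np.asarray(freq_a, dtype=float)) * (
        freq_o - np.asarray(freq_b, dtype=float))


def assign_blocks(panel: GenotypePanel, block_cm: float = 5.0,
                  n_fallback: int = 50) -> np.ndarray:
    """Jackknife block labels per variant.

    Blocks are cut by genetic position (``block_cm`` wide, per chromosome)
    when pos_cM is annotated, otherwise into ``n_fallback`` equal-count
    chunks of the variant order.
    """
    cm = panel.variants["pos_cM"].to_numpy(dtype=float)
    if np.isfinite(cm).all() and panel.n_variants > 0:
        chroms = panel.variants["chrom"].astype(str).to_numpy()
        labels = np.empty(panel.n_variants, dtype=np.int64)
        offset = 0
        for chrom in dict.fromkeys(chroms):
            mask = chroms == chrom
            local = np.floor((cm[mask] - cm[mask].min()) / block_cm).astype(np.int64)
            labels[mask] = local + offset
            offset = labels[mask].max() + 1
        # compress to consecutive labels
        _, labels = np.unique(labels, return_inverse=True)
        return labels
    n = panel.n_variants
    return np.minimum(np.arange(n) * n_fallback // max(n, 1), n_fallback - 1)


def jackknife_se_from_loo(theta: float, theta_loo, weights) -> float:
    """Weighted delete-one-block jackknife SE (Busing et al. convention).

    ``theta`` is the full-data estimate, ``theta_loo`` the leave-one-block-out
    estimates, ``weights`` the block weights (variant counts). Reduces to the
    ordinary delete-one jackknife for equal weights.
    """
    theta_loo = np.asarray(theta_loo, dtype=float)
    m = np.asarray(weights, dtype=float)
    g = theta_loo.size
    if g < 2:
        return float("nan")
    n = m.sum()
    h = n / m
    theta_j = g * theta - ((1.0 - m / n) * theta_loo).sum()
    tau = h * theta - (h - 1.0) * theta_loo
    var = ((tau - theta_j) ** 2 / (h - 1.0)).sum() / g
    return float(np.sqrt(var))


def block_jackknife(values, blocks, weights=None) -> tuple:
    """Weighted block-jackknife mean and SE of per-variant values.

    ``weights`` are per-variant (default 1, so block weights are variant
    counts). Returns ``(estimate, se, n_blocks)``; the SE is NaN with a
    single block.
    """
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    w = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    labels, inverse = np.unique(blocks, return_inverse=True)
    g = labels.size
    sw = np.bincount(inverse, weights=w, minlength=g)
    swv = np.bincount(inverse, weights=w * values, minlength=g)
    total_w = sw.sum()
    total_wv = swv.sum()
    theta = total_wv / total_w
    if g < 2:
        return float(theta), float("nan"), g
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_loo = (total_wv - swv) / (total_w - sw)
    se = jackknife_se_from_loo(float(theta), theta_loo, sw)
    return float(theta), se, g


def f3_scan(panel: GenotypePanel, outgroup: str, sources, targets,
            block_cm: float = 5.0, n_fallback_blocks: int = 50,
            het_correction: bool = False) -> pd.DataFrame:
    """Outgroup-f3 table over all (source, target) pairs.

    Sites must have a defined frequency in the outgroup and in both test
    populations and be polymorphic across the union of the three. With
    ``het_correction`` the outgroup's finite-sample heterozygosity term
    h_o/(2 n_o) is subtracted per site (the corrected variant); the default
    shared-drift form leaves ranking unchanged.
    """
    freq: dict = {}
    count: dict = {}
    het: dict = {}
    for pop in {outgroup, *sources, *targets}:
        freq[pop], count[pop], het[pop] = _pop_site_stats(panel, pop)
    blocks = assign_blocks(panel, block_cm=block_cm, n_fallback=n_fallback_blocks)
    rows = []
    for src in sources:
        for tgt in targets:
            o, a, b = freq[outgroup], freq[src], freq[tgt]
            no, na, nb = count[outgroup], count[src], count[tgt]
            pooled_num = 2 * (no * o + na * a + nb * b)
            pooled_den = 2 * (no + na + nb)
            pooled = pooled_num / pooled_den
            use = (np.isfinite(o) & np.isfinite(a) & np.isfinite(b)
                   & (pooled > 0) & (pooled < 1))
            if not use.any():
                raise ValueError(f"no shared variants for ({outgroup}; {src}, {tgt})")
            vals = outgroup_f3(o[use], a[use], b[use])
            if het_correction:
                vals = vals - het[outgroup][use] / (2.0 * no[use])
            est, se, g = block_jackknife(vals, blocks[use])
            z = est / se if se and np.isfinite(se) and se > 0 else float("nan")
            rows.append(F3Result(outgroup, src, tgt, est, se, z, int(use.sum()), g))
    return pd.DataFrame([r.__dict__ for r in rows])
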