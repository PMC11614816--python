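"""Quality control: LD pruning and relatedness/inbreeding filtering.

Thresholds default to the values used throughout the pipeline: sliding-window
LD pruning (50 SNPs, step 5, r² > 0.5 removed), method-of-moments inbreeding
with F ≥ 0.0156 (second-cousin-offspring) flagged, and KING-robust kinship
with φ > 0.0884 (second-degree) flagged. All statistics use
pairwise-complete observations; r² is the squared Pearson correlation of
genotype dosages, so the module is phase-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panelio import MISSING, GenotypePanel


@dataclass(frozen=True)
class InbreedingResult:
    sample_id: str
    F: float
    raw_F: float
    n_sites: int
    defined: bool = True


@dataclass(frozen=True)
class KinshipResult:
    sample_i: str
    sample_j: str
    phi: float
    n_sites: int
    defined: bool = True


def allele_frequency(panel: GenotypePanel, variant: int, samples=None) -> float:
    """Alt-allele frequency of one variant over a sample subset.

    NaN when every call in the subset is missing (the variant is then
    excluded downstream).
    """
    col = panel.calls[:, variant]
    if samples is not None:
        col = col[np.asarray(samples)]
    obs = col != MISSING
    n = int(obs.sum())
    if n == 0:
        return float("nan")
    return float(col[obs].sum() / (2.0 * n))


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete.

    NaN when fewer than 2 complete pairs or either column is constant on
    the complete pairs (undefined, never coerced to 0).
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def genotype_r2(panel: GenotypePanel, variant_a: int, variant_b: int, samples=None) -> float:
    """Genotype LD r² between two variants over a sample subset."""
    a = panel.calls[:, variant_a]
    b = panel.calls[:, variant_b]
    if samples is not None:
        idx = np.asarray(samples)
        a, b = a[idx], b[idx]
    return _pairwise_r2(a, b)


def _window_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """r² for all column pairs of a dosage block (pairwise-complete)."""
    n, m = calls.shape
    if not (calls == MISSING).any():
        x = calls.astype(float)
        x -= x.mean(axis=0)
        sd = x.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (x.T @ x) / n / np.outer(sd, sd)
        r2 = corr**2
        r2[~np.isfinite(r2)] = np.nan
        return r2
    r2 = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            r2[i, j] = r2[j, i] = _pairwise_r2(calls[:, i], calls[:, j])
    return r2


def prune_ld(panel: GenotypePanel, window_snps: int = 50, step_snps: int = 5,
             r2_max: float = 0.5) -> list:
    """Sliding-window greedy LD pruning; returns kept variant ids.

    Within each window the most correlated violating pair is resolved by
    removing its lower-MAF member (ties: the later position). The window
    then advances by ``step_snps``. Windows never span chromosomes.
    """
    if panel.n_variants == 0:
        return []
    freqs = panel.alt_frequencies()
    maf = np.minimum(freqs, 1 - freqs)
    removed = np.zeros(panel.n_variants, dtype=bool)
    chroms = panel.variants["chrom"].astype(str).to_numpy()
    pos = panel.variants["pos_bp"].to_numpy()

    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step_snps):
            window = idx[start:start + window_snps]
            if len(window) < 2:
                continue
            active = [j for j in window if not removed[j]]
            if len(active) < 2:
                continue
            r2 = _window_r2_matrix(panel.calls[:, active])
            np.fill_diagonal(r2, np.nan)
            alive = np.ones(len(active), dtype=bool)
            while True:
                masked = np.where(np.outer(alive, alive), r2, np.nan)
                iu = np.triu_indices(len(active), k=1)
                vals = masked[iu]
                if not np.any(vals > r2_max):
                    break
                best = np.nanargmax(np.where(vals > r2_max, vals, np.nan))
                a, b = active[iu[0][best]], active[iu[1][best]]
                if maf[a] < maf[b]:
                    victim = a
                elif maf[b] < maf[a]:
                    victim = b
                else:  # tie -> later position
                    victim = a if pos[a] > pos[b] else b
                removed[victim] = True
                alive[active.index(victim)] = False
            if len(window) < window_snps:
                break
    kept = panel.variants["id"][~removed].tolist()
    return kept


def inbreeding_f(panel: GenotypePanel) -> pd.DataFrame:
    """Method-of-moments inbreeding coefficient per sample.

    raw_F = (O_hom − E_hom) / (L − E_hom) over each sample's non-missing
    sites, with E_hom = Σ_k (1 − 2 p_k (1 − p_k) · 2n_k/(2n_k − 1)) from
    panel-wide frequencies; the 2n_k/(2n_k − 1) factor is the standard
    small-sample correction, without which the estimator is biased by about
    −1/(2n) and the inbreeding threshold loses its meaning at modest n.
    Negative values are truncated to zero in ``F`` (kept in ``raw_F``).
    Samples with L ≈ E_hom are flagged undefined.
    """
    p = panel.alt_frequencies()
    n_k = (panel.calls != MISSING).sum(axis=0)
    usable = np.isfinite(p) & (n_k >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssc = 2.0 * n_k / np.maximum(2.0 * n_k - 1.0, 1.0)
    e_site = 1.0 - 2.0 * p * (1.0 - p) * ssc
    calls = panel.calls[:, usable]
    e_site = e_site[usable]
    obs = calls != MISSING
    hom = (calls == 0) | (calls == 2)
    L = obs.sum(axis=1).astype(float)
    O_hom = (hom & obs).sum(axis=1).astype(float)
    E_hom = obs @ e_site
    denom = L - E_hom
    defined = np.abs(denom) > 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(defined, (O_hom - E_hom) / denom, np.nan)
    return pd.DataFrame({
        "sample_id": panel.samples["id"],
        "raw_F": raw,
        "F": np.where(defined, np.maximum(raw, 0.0), np.nan),
        "n_sites": L.astype(int),
        "defined": defined,
    })


def king_kinship(panel: GenotypePanel, i: int, j: int) -> KinshipResult:
    """KING-robust kinship for one sample pair.

    φ = (N_both_het − 2·N_opposite_hom) / (N_het_i + N_het_j) over
    pairwise-complete sites; opposite homozygotes are dosage pairs (0,2)
    or (2,0). A zero denominator flags the pair undefined (treated as
    unrelated downstream).
    """
    a = panel.calls[i]
    b = panel.calls[j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    het_i = int((a == 1).sum())
    het_j = int((b == 1).sum())
    both_het = int(((a == 1) & (b == 1)).sum())
    opp_hom = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    denom = het_i + het_j
    ids = panel.samples["id"]
    if denom == 0:
        return KinshipResult(ids[i], ids[j], float("nan"), int(ok.sum()), False)
    phi = (both_het - 2.0 * opp_hom) / denom
    return KinshipResult(ids[i], ids[j], float(phi), int(ok.sum()))


def kinship_matrix(panel: GenotypePanel) -> pd.DataFrame:
    """KING-robust φ for every unordered sample pair (long format)."""
    calls = panel.calls
    obs = calls != MISSING
    het = (calls == 1) & obs
    hom0 = calls == 0
    hom2 = calls == 2
    O = obs.astype(np.float64)
    H = het.astype(np.float64)
    both_het = H @ H.T
    opp = hom0.astype(np.float64) @ hom2.astype(np.float64).T
    opp_hom = opp + opp.T
    het_given_obs = H @ O.T  # het in row-sample at sites observed in both
    denom = het_given_obs + het_given_obs.T
    n_sites = O @ O.T
    rows = []
    ids = panel.samples["id"].tolist()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = denom[i, j]
            phi = (both_het[i, j] - 2.0 * opp_hom[i, j]) / d if d > 0 else float("nan")
            rows.append((ids[i], ids[j], phi, int(n_sites[i, j]), d > 0))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "phi", "n_sites", "defined"])


def relatedness_filter(panel: GenotypePanel, f_max: float = 0.0156,
                       kin_max: float = 0.0884, pca_outliers=(),
                       exempt_populations=()) -> tuple:
    """Remove inbred, related, and PCA-outlier samples.

    Filter order: inbreeding (F ≥ ``f_max``) → kinship (φ > ``kin_max``,
    dropping the pair member with more missing calls, ties to the later
    sample) → listed PCA outliers. Samples from ``exempt_populations`` are
    never removed. Returns ``(filtered_panel, report)`` where the report
    lists (sample_id, reason, value) per removal.
    """
    exempt = set(exempt_populations)
    pops = panel.samples["population"].tolist()
    ids = panel.samples["id"].tolist()
    pos_of = {s: k for k, s in enumerate(ids)}
    removed: dict = {}

    ftab = inbreeding_f(panel)
    for k, row in ftab.iterrows():
        if row["defined"] and row["F"] >= f_max and pops[k] not in exempt:
            removed[row["sample_id"]] = ("inbreeding", float(row["F"]))

    ktab = kinship_matrix(panel)
    miss = panel.missing_per_sample()
    viol = ktab[ktab["defined"] & (ktab["phi"] > kin_max)].copy()
    viol = viol.sort_values("phi", ascending=False, kind="stable")
    for _, row in viol.iterrows():
        a, b = row["sample_i"], row["sample_j"]
        if a in removed or b in removed:
            continue
        ia, ib = pos_of[a], pos_of[b]
        a_ex, b_ex = pops[ia] in exempt, pops[ib] in exempt
        if a_ex and b_ex:
            continue
        if a_ex:
            victim = b
        elif b_ex:
            victim = a
        elif miss[ia] > miss[ib]:
            victim = a
        elif miss[ib] > miss[ia]:
            victim = b
        else:  # tie -> later sample order
            victim = b if ib > ia else a
        removed[victim] = ("kinship", float(row["phi"]))

    for sid in pca_outliers:
        if sid in removed or sid not in pos_of:
            continue
        if pops[pos_of[sid]] in exempt:
            continue
        removed[sid] = ("pca_outlier", float("nan"))

    keep = np.array([sid not in removed for sid in ids])
    report = pd.DataFrame(
        [(sid, reason, value) for sid, (reason, value) in removed.items()],
        columns=["sample_id", "reason", "value"],
    )
    return panel.take_samples(keep), report
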