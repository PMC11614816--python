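"""Synthetic genotype panels with known structure, LD, and split times.

Three generators, each bit-reproducible under a fixed seed, give every
pipeline stage a parameter-recovery target:

- :func:`balding_nichols_panel` — multi-population differentiation with a
  target FST (beta-distributed population frequencies around a uniform
  ancestral frequency; genotypes binomial). Exercises PCA, FST and f3.
- :func:`wright_fisher_forward` — an individual-based diploid
  Wright–Fisher population with crossover on a uniform genetic map and
  recurrent mutation, so the LD decay of the emitted panel encodes a known
  effective size. Exercises the LD → Ne chain.
- :func:`split_pair_sim` — two daughter populations drifting independently
  for T generations after a clean split from a common ancestor, the model
  under which FST = 1 − (1 − 1/(2Ne))^T holds exactly in expectation.
  Exercises FST → divergence-time inference end to end.

Drift in ``split_pair_sim`` acts on allele frequencies rather than
individuals: exact for the FST/T relation and orders of magnitude faster.
The individual-based simulator is reserved for LD tests where linkage
matters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panelio import GeneticMap, GenotypePanel

_POP_NAMES = [f"pop{i+1}" for i in range(26)]


def _variant_table(n_snps: int, chrom: str = "1", spacing_bp: int = 10_000,
                   pos_cm=None) -> pd.DataFrame:
    pos_bp = spacing_bp * (1 + np.arange(n_snps))
    return pd.DataFrame({
        "chrom": chrom,
        "pos_bp": pos_bp,
        "id": [f"snp{j+1}" for j in range(n_snps)],
        "ref_allele": "A",
        "alt_allele": "G",
        "pos_cM": np.nan if pos_cm is None else pos_cm,
    })


def _sample_table(counts: dict) -> pd.DataFrame:
    rows = []
    for pop, n in counts.items():
        rows += [{"id": f"{pop}_s{i+1}", "population": pop, "group_tags": ""}
                 for i in range(n)]
    return pd.DataFrame(rows)


def balding_nichols_panel(n_pops: int = 2, n_samples: int = 100,
                          n_snps: int = 20_000, fst: float = 0.1,
                          seed: int = 0, pop_names=None) -> GenotypePanel:
    """Structured panel with target differentiation ``fst``.

    Ancestral frequencies are Uniform(0.05, 0.95); each population's
    frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) so that E[FST] ≈ F, and
    genotypes are Binomial(2, p_pop). ``fst`` may be a scalar or one value
    per population; F = 0 copies the ancestral frequency exactly.
    """
    rng = np.random.default_rng(seed)
    fst_per_pop = np.broadcast_to(np.asarray(fst, dtype=float), (n_pops,))
    if ((fst_per_pop < 0) | (fst_per_pop >= 1)).any():
        raise ValueError("target fst must be in [0, 1)")
    names = list(pop_names) if pop_names else _POP_NAMES[:n_pops]
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    blocks = []
    for F in fst_per_pop:
        if F == 0.0:
            p_pop = p_anc
        else:
            ratio = (1.0 - F) / F
            p_pop = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
        blocks.append(rng.binomial(2, p_pop, size=(n_samples, n_snps)))
    calls = np.vstack(blocks).astype(np.int8)
    return GenotypePanel(
        _variant_table(n_snps),
        _sample_table({name: n_samples for name in names}),
        calls,
    )


def wright_fisher_forward(n_diploid: int = 100, n_generations: int = None,
                          chromosome_length_cm: float = 50.0,
                          n_chromosomes: int = 10, n_sites: int = 6000,
                          mutation_rate: float = 5e-5, seed: int = 0,
                          sample_size: int = None, min_maf: float = 0.05,
                          population: str = "pop1") -> tuple:
    """Forward diploid Wright–Fisher simulation with recombination.

    ``n_diploid`` individuals reproduce for ``n_generations`` (default
    10·N, a burn-in long enough for LD to equilibrate) carrying
    ``n_chromosomes`` chromosomes that together span
    ``chromosome_length_cm``, with ``n_sites`` total sites evenly spaced
    on a uniform genetic map. Crossovers are Poisson along each
    chromosome's map; chromosomes assort independently; recurrent
    symmetric mutation at ``mutation_rate`` per site per transmitted
    gamete keeps variation segregating. Several chromosomes matter: with
    one short chromosome a single deep genealogy dominates the realized
    LD, and the panel's r² decay is far noisier than array data.

    Returns ``(panel, genetic_map)`` with the final generation's genotypes
    at segregating sites of minor-allele frequency ≥ ``min_maf`` (array
    panels are ascertained toward common variants, and the LD → Ne
    machinery assumes that) and pos_cM pre-annotated.
    """
    if n_diploid < 20:
        raise ValueError("need at least 20 diploids")
    if n_generations is None:
        n_generations = 10 * n_diploid
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_diploid
    chrom_cm = chromosome_length_cm / n_chromosomes
    sites_per_chrom = n_sites // n_chromosomes
    chrom_site_cm = np.linspace(0.0, chrom_cm, sites_per_chrom)
    chrom_morgans = chrom_cm / 100.0
    n_sites = sites_per_chrom * n_chromosomes

    hap = (rng.random((n_hap, n_sites))
           < rng.uniform(0.05, 0.95, n_sites)).astype(np.int8)

    slices = [slice(c * sites_per_chrom, (c + 1) * sites_per_chrom)
              for c in range(n_chromosomes)]
    for _ in range(n_generations):
        parents = rng.integers(0, n_diploid, size=n_hap)  # one parent per gamete
        h0 = hap[2 * parents]
        h1 = hap[2 * parents + 1]
        new = np.empty_like(hap)
        for sl in slices:
            n_cross = rng.poisson(chrom_morgans, size=n_hap)
            starts = rng.integers(0, 2, size=n_hap)
            cross_counts = np.zeros((n_hap, sites_per_chrom), dtype=np.int64)
            total = int(n_cross.sum())
            if total:
                gidx = np.repeat(np.arange(n_hap), n_cross)
                bp_cm = rng.uniform(0.0, chrom_cm, size=total)
                sidx = np.searchsorted(chrom_site_cm, bp_cm, side="left")
                np.add.at(cross_counts, (gidx, sidx), 1)
            parity = (np.cumsum(cross_counts, axis=1) + starts[:, None]) % 2
            new[:, sl] = np.where(parity == 0, h0[:, sl], h1[:, sl])
        hap = new
        n_mut = rng.poisson(mutation_rate * n_hap * n_sites)
        if n_mut:
            flat = rng.integers(0, n_hap * n_sites, size=n_mut)
            hap.reshape(-1)[flat] ^= 1

    freq = hap.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    seg = maf >= max(min_maf, 1.0 / n_hap)
    if not seg.any():
        raise RuntimeError(
            "population lost all polymorphism; increase mutation_rate or n_sites")
    if sample_size is None:
        sample_size = n_diploid
    genotypes = (hap[0::2] + hap[1::2])[:sample_size, seg].astype(np.int8)

    chrom_labels = np.repeat([str(c + 1) for c in range(n_chromosomes)],
                             sites_per_chrom)[seg]
    site_cm = np.tile(chrom_site_cm, n_chromosomes)[seg]
    pos_bp = (1 + np.round(site_cm * 1e6)).astype(np.int64)  # 1 cM ~ 1 Mb
    variants = pd.DataFrame({
        "chrom": chrom_labels,
        "pos_bp": pos_bp,
        "id": [f"snp{j+1}" for j in range(seg.sum())],
        "ref_allele": "A",
        "alt_allele": "G",
        "pos_cM": site_cm,
    })
    panel = GenotypePanel(variants, _sample_table({population: sample_size}),
                          genotypes)
    end_bp = int(1 + round(chrom_cm * 1e6))
    gmap = GeneticMap({str(c + 1): (np.array([1, end_bp]),
                                    np.array([0.0, chrom_cm]))
                       for c in range(n_chromosomes)})
    return panel, gmap


def split_pair_sim(ne: int = 500, t_generations: int = 200,
                   n_snps: int = 20_000, n_samples: int = 100,
                   seed: int = 0, pop_names=("pop1", "pop2")) -> GenotypePanel:
    """Two populations drifting independently for T generations after a split.

    Ancestral frequencies are Uniform(0.05, 0.95); each daughter frequency
    takes ``t_generations`` rounds of Binomial(2·Ne) drift. Genotypes are
    sampled from the final frequencies, so the expected differentiation is
    FST = 1 − (1 − 1/(2Ne))^T.
    """
    if ne < 50:
        raise ValueError("ne must be >= 50")
    if t_generations < 0:
        raise ValueError("t_generations must be >= 0")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    two_ne = 2 * ne
    blocks = []
    for _pop in pop_names:
        p = p_anc.copy()
        for _ in range(t_generations):
            p = rng.binomial(two_ne, p) / two_ne
        blocks.append(rng.binomial(2, p, size=(n_samples, n_snps)))
    calls = np.vstack(blocks).astype(np.int8)
    return GenotypePanel(
        _variant_table(n_snps),
        _sample_table({name: n_samples for name in pop_names}),
        calls,
    )
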