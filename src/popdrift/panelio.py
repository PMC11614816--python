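"""Genotype panels, genetic maps, and their file formats.

The central container is :class:`GenotypePanel`: a samples × variants matrix
of alt-allele dosages in ``{0, 1, 2}`` with :data:`MISSING` (``-1``) as the
missing-call sentinel, plus variant and sample metadata tables. Readers and
writers cover PLINK 1 binary (bed/bim/fam, SNP-major), VCF with diploid GT
calls, whitespace-delimited genetic maps (chrom, bp, cM), and a TSV
sample→population table.

Coordinates are 1-based base-pair positions as in VCF/bim. Genetic positions
(cM) are attached by linear interpolation in a :class:`GeneticMap`; positions
outside the map range are clamped to the boundary cM value rather than
extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("popdrift")

#: Sentinel for a missing genotype call; never a valid dosage.
MISSING = np.int8(-1)

VARIANT_COLUMNS = ["chrom", "pos_bp", "id", "ref_allele", "alt_allele", "pos_cM"]
SAMPLE_COLUMNS = ["id", "population", "group_tags"]

# PLINK 1 .bed: magic, then SNP-major 2-bit codes.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> alt (A1) dosage. 0b01 is the PLINK missing code.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class PanelFormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _variant_frame(records: dict) -> pd.DataFrame:
    df = pd.DataFrame(records)
    if "pos_cM" not in df.columns:
        df["pos_cM"] = np.nan
    return df[VARIANT_COLUMNS].reset_index(drop=True)


def _sample_frame(records: dict) -> pd.DataFrame:
    df = pd.DataFrame(records)
    if "population" not in df.columns:
        df["population"] = "unknown"
    if "group_tags" not in df.columns:
        df["group_tags"] = ""
    return df[SAMPLE_COLUMNS].reset_index(drop=True)


@dataclass
class GenotypePanel:
    """Samples × biallelic variants with alt-allele dosage calls.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos_bp, id, ref_allele,
        alt_allele, pos_cM`` (``pos_cM`` is NaN until map-annotated).
        Within a chromosome rows are sorted by ``pos_bp``.
    samples : pandas.DataFrame
        One row per sample with columns ``id, population, group_tags``;
        ids are unique.
    calls : numpy.ndarray
        ``(n_samples, n_variants)`` int8 matrix of alt-allele dosages with
        ``MISSING`` (-1) for no-calls.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise PanelFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise PanelFormatError("calls contain values outside {MISSING,0,1,2}")
        if self.samples["id"].duplicated().any():
            dups = self.samples["id"][self.samples["id"].duplicated()].tolist()
            raise PanelFormatError(f"duplicate sample ids: {dups}")

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["population"]))

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples in population {population!r}")
        return idx

    def take_samples(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            variants=self.variants.copy(),
            samples=self.samples.iloc[index].reset_index(drop=True),
            calls=self.calls[index].copy(),
        )

    def take_variants(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=self.samples.copy(),
            calls=self.calls[:, index].copy(),
        )

    def alt_frequencies(self, sample_index=None) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing calls (NaN if none)."""
        calls = self.calls if sample_index is None else self.calls[sample_index]
        obs = calls != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def missing_per_sample(self) -> np.ndarray:
        return (self.calls == MISSING).sum(axis=1)


@dataclass
class GeneticMap:
    """Per-chromosome monotone bp → cM mapping.

    ``points`` maps a chromosome label to ``(pos_bp, pos_cM)`` arrays with
    ``pos_bp`` strictly increasing and ``pos_cM`` non-decreasing.
    """

    points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (bp, cm) in self.points.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if bp.size != cm.size or bp.size == 0:
                raise PanelFormatError(f"map for {chrom}: empty or mismatched columns")
            if np.any(np.diff(bp) <= 0):
                raise PanelFormatError(f"map for {chrom}: pos_bp not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise PanelFormatError(f"map for {chrom}: pos_cM decreasing")
            clean[str(chrom)] = (bp, cm)
        self.points = clean

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a whitespace-delimited (chrom, pos_bp, pos_cM) table.

        A header line is tolerated (skipped when the bp column is not numeric).
        """
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
        if df.shape[1] < 3:
            raise PanelFormatError("genetic map needs >=3 columns: chrom pos_bp cM")
        first = str(df.iloc[0, 1])
        try:
            float(first)
        except ValueError:
            df = df.iloc[1:]
        points = {}
        for chrom, grp in df.groupby(0, sort=False):
            bp = grp[1].astype(np.int64).to_numpy()
            cm = grp[2].astype(float).to_numpy()
            order = np.argsort(bp, kind="stable")
            points[str(chrom)] = (bp[order], cm[order])
        return cls(points)

    def interpolate(self, chrom: str, pos_bp) -> np.ndarray:
        """cM positions by linear interpolation, clamped at the map boundaries."""
        chrom = str(chrom)
        if chrom not in self.points:
            raise KeyError(
                f"chromosome {chrom!r} absent from map "
                f"(have {sorted(self.points)})"
            )
        bp, cm = self.points[chrom]
        return np.interp(np.asarray(pos_bp, dtype=float), bp, cm)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (bp, cm) in self.points.items():
                for b, c in zip(bp, cm):
                    fh.write(f"{chrom}\t{b}\t{c:.8g}\n")


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypePanel:
    """Read a PLINK 1 bed/bim/fam trio into a :class:`GenotypePanel`.

    The bim A1 allele is taken as the counted (alt) allele, so bed code
    ``00`` decodes to dosage 2 and ``11`` to 0; the PLINK missing code
    ``01`` maps to :data:`MISSING`. The fam family id is used as the
    population label.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "pos_cM", "pos_bp", "a1", "a2"], dtype=str,
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    for _, row in bim.iterrows():
        if row["a1"] == row["a2"]:
            raise PanelFormatError(f"variant {row['id']}: identical alleles (non-biallelic row)")

    n_samples, n_variants = len(fam), len(bim)
    bytes_per_variant = (n_samples + 3) // 4
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise PanelFormatError(f"{bed_path}: not a SNP-major PLINK 1 bed file")
    body = raw[3:]
    if body.size != bytes_per_variant * n_variants:
        raise PanelFormatError(
            f"{bed_path}: payload is {body.size} bytes, expected "
            f"{bytes_per_variant * n_variants} for {n_samples}x{n_variants}"
        )
    blocks = body.reshape(n_variants, bytes_per_variant)
    # Unpack 2-bit codes, sample-major within each variant, low bits first.
    codes = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    calls = _BED_DECODE[codes[:, :n_samples]].T  # samples x variants

    cm = pd.to_numeric(bim["pos_cM"], errors="coerce")
    variants = _variant_frame({
        "chrom": bim["chrom"],
        "pos_bp": bim["pos_bp"].astype(np.int64),
        "id": bim["id"],
        "ref_allele": bim["a2"],
        "alt_allele": bim["a1"],
        "pos_cM": cm.where(cm != 0.0, np.nan),
    })
    samples = _sample_frame({"id": fam["iid"], "population": fam["fid"]})
    return GenotypePanel(variants, samples, calls)


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write bed/bim/fam (SNP-major, padding bits zero)."""
    prefix = Path(prefix)
    n_samples, n_variants = panel.n_samples, panel.n_variants
    bytes_per_variant = (n_samples + 3) // 4
    codes = np.zeros((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    calls = panel.calls.T  # variants x samples
    for dosage, code in _BED_ENCODE.items():
        codes[:, :n_samples][calls == dosage] = code
    blocks = np.zeros((n_variants, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        blocks |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(blocks.tobytes())

    v = panel.variants
    cm = v["pos_cM"].fillna(0.0)
    bim = pd.DataFrame({
        "chrom": v["chrom"], "id": v["id"], "pos_cM": cm,
        "pos_bp": v["pos_bp"], "a1": v["alt_allele"], "a2": v["ref_allele"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    s = panel.samples
    fam = pd.DataFrame({
        "fid": s["population"], "iid": s["id"],
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path) -> GenotypePanel:
    """Read diploid biallelic GT calls from a VCF.

    ``0/0 → 0``, ``0/1``/``1/0 → 1``, ``1/1 → 2``, ``./. → MISSING``.
    Multi-allelic records and records with haploid/malformed GT fields are
    skipped; the skip count is logged and stored on the returned panel as
    ``panel.n_skipped_records``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, columns = [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        if any(len(g) != 3 for g in rec.genotypes):  # [a, b, phased] per sample
            n_skipped += 1
            continue
        gt = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        rows.append({
            "chrom": rec.CHROM, "pos_bp": rec.POS,
            "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
            "ref_allele": rec.REF, "alt_allele": rec.ALT[0],
        })
        columns.append(gt)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/malformed records", n_skipped)
    calls = (np.vstack(columns).T if columns
             else np.zeros((len(sample_ids), 0), dtype=np.int8))
    panel = GenotypePanel(
        _variant_frame(rows) if rows else _variant_frame(
            {c: [] for c in VARIANT_COLUMNS[:-1]}),
        _sample_frame({"id": sample_ids}),
        calls,
    )
    panel.n_skipped_records = n_skipped
    return panel


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as a minimal uncompressed VCF v4.2 with GT only."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples["id"]) + "\n")
        for j, v in panel.variants.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in panel.calls[:, j])
            fh.write(f"{v['chrom']}\t{v['pos_bp']}\t{v['id']}\t"
                     f"{v['ref_allele']}\t{v['alt_allele']}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Population table
# ---------------------------------------------------------------------------

def read_population_table(path) -> pd.DataFrame:
    """TSV with columns (id, population[, tags]); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if str(df.iloc[0, 0]).lower() in {"id", "sample", "sample_id", "iid"}:
        df = df.iloc[1:]
    df = df.reset_index(drop=True)
    out = pd.DataFrame({"id": df[0], "population": df[1]})
    out["group_tags"] = df[2] if df.shape[1] > 2 else ""
    out["group_tags"] = out["group_tags"].fillna("")
    return out


def assign_populations(panel: GenotypePanel, table: pd.DataFrame) -> GenotypePanel:
    """Return a panel with populations (and tags) taken from a sample table."""
    lookup = table.set_index("id")
    samples = panel.samples.copy()
    known = samples["id"].isin(lookup.index)
    samples.loc[known, "population"] = lookup.loc[
        samples.loc[known, "id"], "population"].to_numpy()
    samples.loc[known, "group_tags"] = lookup.loc[
        samples.loc[known, "id"], "group_tags"].to_numpy()
    return GenotypePanel(panel.variants.copy(), samples, panel.calls.copy())


# ---------------------------------------------------------------------------
# Merging and map annotation
# ---------------------------------------------------------------------------

def merge_panels(panels: list) -> GenotypePanel:
    """Merge ≥2 panels on the intersection of (chrom, pos_bp, allele pair).

    Alleles reconcile by exact match, or by ref/alt swap with dosage flip
    ``d → 2−d``. Strand-ambiguous A/T and C/G sites must match exactly.
    Irreconcilable variants are dropped and counted
    (``merged.n_dropped_variants``). Samples are concatenated; duplicate
    sample ids raise.
    """
    if len(panels) < 2:
        raise ValueError("merge_panels needs at least two panels")

    base = panels[0]
    key_of = {}
    for j, v in base.variants.iterrows():
        key_of[(str(v["chrom"]), int(v["pos_bp"]))] = j

    # orientation[i] holds (source column, flip?) per panel, per kept key
    keep_keys = list(key_of)
    orientations = [{k: (key_of[k], False) for k in keep_keys}]
    n_dropped = 0
    for panel in panels[1:]:
        this = {}
        for j, v in panel.variants.iterrows():
            this[(str(v["chrom"]), int(v["pos_bp"]))] = j
        resolved = {}
        for k in keep_keys:
            if k not in this:
                continue
            b = base.variants.iloc[key_of[k]]
            o = panel.variants.iloc[this[k]]
            pair_b = (b["ref_allele"], b["alt_allele"])
            pair_o = (o["ref_allele"], o["alt_allele"])
            if pair_o == pair_b:
                resolved[k] = (this[k], False)
            elif pair_o == pair_b[::-1] and pair_b not in _AMBIGUOUS_PAIRS:
                resolved[k] = (this[k], True)
            else:
                n_dropped += 1
        keep_keys = [k for k in keep_keys if k in resolved]
        orientations.append(resolved)

    keep_keys.sort(key=lambda k: (k[0], k[1]))
    base_idx = [key_of[k] for k in keep_keys]

    blocks = []
    for panel, orient in zip(panels, orientations):
        cols = np.empty((panel.n_samples, len(keep_keys)), dtype=np.int8)
        for out_j, k in enumerate(keep_keys):
            src_j, flip = orient[k]
            col = panel.calls[:, src_j]
            if flip:
                col = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
            cols[:, out_j] = col
        blocks.append(cols)

    samples = pd.concat([p.samples for p in panels], ignore_index=True)
    merged = GenotypePanel(
        base.variants.iloc[base_idx].reset_index(drop=True),
        samples,
        np.vstack(blocks),
    )
    merged.n_dropped_variants = n_dropped
    if n_dropped:
        logger.info("merge_panels: dropped %d irreconcilable variants", n_dropped)
    return merged


def annotate_genetic_positions(panel: GenotypePanel, gmap: GeneticMap) -> GenotypePanel:
    """Attach pos_cM to every variant by interpolation in the genetic map."""
    chroms = panel.variants["chrom"].astype(str).unique()
    absent = [c for c in chroms if c not in gmap.points]
    if absent:
        raise KeyError(f"chromosomes absent from map: {absent}")
    variants = panel.variants.copy()
    cm = np.empty(len(variants))
    for chrom in chroms:
        mask = (variants["chrom"].astype(str) == chrom).to_numpy()
        cm[mask] = gmap.interpolate(chrom, variants.loc[mask, "pos_bp"].to_numpy())
    variants["pos_cM"] = cm
    return GenotypePanel(variants, panel.samples.copy(), panel.calls.copy())
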