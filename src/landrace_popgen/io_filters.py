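"""Reading, validation, filtering, polarization and LD pruning of genotypes.

The VCF is the canonical interchange format: genotypes arrive as biallelic
SNP records with an array-style quality class in ``INFO/QC`` and an optional
ancestral-allele annotation in ``INFO/AA``. Companion tables (population
map, coordinates, GERP scores, bioclim, gene intervals) are plain TSV/BED.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Affymetrix array quality classes retained by default.
DEFAULT_QUALITY_WHITELIST = (
    "PolyHighResolution",
    "MonoHighResolution",
    "NoMinorHom",
)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_popmap(path) -> pd.DataFrame:
    """Read a sample→population TSV with columns ``sample, population``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "population"} <= set(df.columns):
        raise ValueError(f"popmap {path} must have columns sample, population")
    dup = df["sample"][df["sample"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicated samples in popmap: {dup}")
    return df


def read_coordinates(path) -> pd.DataFrame:
    """Population coordinates TSV: population, latitude, longitude[, cluster]."""
    df = pd.read_csv(path, sep="\t")
    need = {"population", "latitude", "longitude"}
    if not need <= set(df.columns):
        raise ValueError(f"coordinates {path} must have columns {sorted(need)}")
    if (df["latitude"].abs() > 90).any() or (df["longitude"].abs() > 180).any():
        raise ValueError("coordinates out of range")
    return df


def read_gerp(path) -> pd.DataFrame:
    """GERP track TSV: chrom, pos (1-based), gerp_score."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos", "gerp_score"} <= set(df.columns):
        raise ValueError(f"GERP table {path} needs chrom, pos, gerp_score")
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom,pos) in GERP table")
    if not np.isfinite(df["gerp_score"]).all():
        raise ValueError("non-finite GERP scores")
    return df


def read_bioclim(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "population" not in df.columns:
        raise ValueError(f"bioclim {path} needs a population column")
    return df


def read_genes_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open) → 1-based inclusive."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    df["start"] = df["start"].astype(int) + 1  # BED is 0-based half-open
    df["end"] = df["end"].astype(int)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_fourfold_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError(f"fourfold list {path} needs chrom, pos columns")
    return df


def read_genotypes(vcf_path, popmap_path) -> GenotypePanel:
    """Load a VCF into a :class:`GenotypePanel` with alt-allele dosages.

    Missing calls (``./.``) become :data:`MISSING`. The ancestral allele is
    taken from ``INFO/AA`` when present, else recorded as ``"."`` (unknown);
    the site quality class from ``INFO/QC`` (empty string when absent).
    Multi-allelic records are kept as single rows flagged for
    :func:`filter_sites`, never silently split.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    pop_of_sample = dict(zip(popmap["sample"], popmap["population"]))

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_of_sample]
    if absent:
        raise ValueError(f"VCF samples missing from popmap: {absent}")

    rows = []
    dosages = []
    for var in vcf:
        alt = ",".join(var.ALT) if var.ALT else "."
        aa = var.INFO.get("AA")
        qc = var.INFO.get("QC")
        rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": alt,
                "ancestral": str(aa) if aa is not None else ".",
                "quality_class": str(qc) if qc is not None else "",
            }
        )
        gt = var.gt_types.astype(np.int8)  # 0,1,2 = alt dosage; 3 = missing
        gt[gt == 3] = MISSING
        dosages.append(gt)
    vcf.close()

    sites = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "ancestral", "quality_class"],
    )
    dosage = (
        np.stack(dosages, axis=1)
        if dosages
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypePanel(
        sample_ids=samples,
        pop_of_sample={s: pop_of_sample[s] for s in samples},
        sites=sites,
        dosage=dosage,
    )


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a panel as an uncompressed VCFv4.2 with INFO/AA and INFO/QC.

    Derived-coded panels are converted back to ref/alt coding on write so
    that the emitted file is a standards-compliant VCF; reading it back and
    re-polarizing reproduces the derived dosages.
    """
    dosage = panel.dosage
    if panel.coding == "derived":
        flip = (panel.sites["ancestral"] == panel.sites["alt"]).to_numpy()
        dosage = dosage.copy()
        block = dosage[:, flip]
        called = block != MISSING
        block[called] = 2 - block[called]
        dosage[:, flip] = block

    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write(
            '##INFO=<ID=QC,Number=1,Type=String,Description="Array quality class">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        sites = panel.sites
        for j in range(panel.n_sites):
            s = sites.iloc[j]
            info = []
            if s["ancestral"] not in (".", "", None):
                info.append(f"AA={s['ancestral']}")
            if s["quality_class"]:
                info.append(f"QC={s['quality_class']}")
            info_str = ";".join(info) if info else "."
            gts = "\t".join(gt_str[int(d)] for d in dosage[:, j])
            fh.write(
                f"{s['chrom']}\t{s['pos']}\t.\t{s['ref']}\t{s['alt']}\t.\t.\t"
                f"{info_str}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _is_snp(ref: str, alt: str) -> bool:
    alleles = [ref] + alt.split(",")
    return all(len(a) == 1 and a in VALID_BASES for a in alleles)


def filter_sites(
    panel: GenotypePanel,
    quality_whitelist: tuple[str, ...] | None = DEFAULT_QUALITY_WHITELIST,
    drop_indels: bool = True,
    biallelic_only: bool = True,
    max_site_missing: float = 1.0,
    drop_monomorphic: bool = False,
) -> GenotypePanel:
    """Apply array-style site filters; records per-filter attrition.

    A site survives if it is a non-indel SNP (when ``drop_indels``),
    biallelic (when ``biallelic_only``), carries a whitelisted quality
    class (when a whitelist is given), has missing fraction ≤
    ``max_site_missing``, and (when ``drop_monomorphic``) is polymorphic
    among called genotypes. Raises if nothing survives, reporting the
    attrition per rule.
    """
    if quality_whitelist is not None and len(quality_whitelist) == 0:
        raise ValueError("quality_whitelist must be non-empty when given")

    sites = panel.sites
    n = len(sites)
    keep = np.ones(n, dtype=bool)
    attrition: dict[str, int] = {}

    snp_ok = np.fromiter(
        (_is_snp(r, a) for r, a in zip(sites["ref"], sites["alt"])),
        dtype=bool,
        count=n,
    )
    if drop_indels:
        attrition["indel"] = int((keep & ~snp_ok).sum())
        keep &= snp_ok
    if biallelic_only:
        bi = ~sites["alt"].str.contains(",").to_numpy() & (sites["alt"] != ".")
        attrition["multiallelic"] = int((keep & ~bi).sum())
        keep &= bi
    if quality_whitelist is not None:
        q_ok = sites["quality_class"].isin(quality_whitelist).to_numpy()
        attrition["quality_class"] = int((keep & ~q_ok).sum())
        keep &= q_ok
    miss_ok = panel.site_missing_fraction() <= max_site_missing
    attrition["missingness"] = int((keep & ~miss_ok).sum())
    keep &= miss_ok
    if drop_monomorphic:
        ac, an = panel.allele_counts()
        poly = (ac > 0) & (ac < an)
        attrition["monomorphic"] = int((keep & ~poly).sum())
        keep &= poly

    if not keep.any():
        raise ValueError(f"all sites removed by filters; attrition={attrition}")
    out = panel.take_sites(keep)
    out.history.append({"stage": "filter_sites", "attrition": attrition,
                        "n_in": n, "n_out": int(keep.sum())})
    logger.info("filter_sites: %d -> %d sites, attrition=%s",
                n, int(keep.sum()), attrition)
    return out


def _window_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise squared genotype correlation; missing handled pairwise."""
    d = dosage.astype(float)
    d[dosage == MISSING] = np.nan
    cols = d.shape[1]
    r2 = np.zeros((cols, cols))
    for i in range(cols):
        for j in range(i + 1, cols):
            both = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            if both.sum() < 2:
                continue
            x, y = d[both, i], d[both, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
            r2[i, j] = r2[j, i] = r * r
    return r2


def ld_prune(
    panel: GenotypePanel,
    window: int = 500,
    step: int = 200,
    n_iter: int = 5,
    r2_max: float = 0.1,
    window_unit: str = "variants",
) -> GenotypePanel:
    """Sliding-window LD pruning of the dosage matrix.

    Within each window, for every retained pair whose squared genotype
    correlation exceeds ``r2_max`` the later site is removed; the scan is
    repeated ``n_iter`` times or until no further removal. ``window_unit``
    chooses whether ``window``/``step`` count variants (the default,
    matching the array-genotype convention) or base pairs.
    """
    if not 0 <= r2_max <= 1:
        raise ValueError("r2_max must be in [0, 1]")
    if window < step or step < 1:
        raise ValueError("require window >= step >= 1")
    if window_unit not in ("variants", "bp"):
        raise ValueError("window_unit must be 'variants' or 'bp'")

    keep = np.ones(panel.n_sites, dtype=bool)
    chroms = panel.sites["chrom"].to_numpy()
    pos = panel.sites["pos"].to_numpy()

    for _ in range(n_iter):
        removed_this_iter = 0
        for chrom in pd.unique(chroms):
            cidx = np.flatnonzero(chroms == chrom)
            if window_unit == "variants":
                starts = range(0, len(cidx), step)
                windows = [cidx[s:s + window] for s in starts]
            else:
                p = pos[cidx]
                windows = []
                start = p.min()
                while start <= p.max():
                    windows.append(cidx[(p >= start) & (p < start + window)])
                    start += step
            for widx in windows:
                live = widx[keep[widx]]
                if len(live) < 2:
                    continue
                r2 = _window_r2(panel.dosage[:, live])
                alive = np.ones(len(live), dtype=bool)
                for i in range(len(live)):
                    if not alive[i]:
                        continue
                    for j in range(i + 1, len(live)):
                        if alive[j] and r2[i, j] > r2_max:
                            alive[j] = False
                            removed_this_iter += 1
                keep[live[~alive]] = False
        if removed_this_iter == 0:
            break

    out = panel.take_sites(keep)
    out.history.append({"stage": "ld_prune", "n_in": panel.n_sites,
                        "n_out": int(keep.sum())})
    return out


def polarize_to_ancestral(panel: GenotypePanel) -> GenotypePanel:
    """Recode dosages to count derived alleles using INFO/AA.

    Sites where the ancestral allele equals REF keep their dosages; where
    it equals ALT, dosages are flipped d → 2−d (MISSING preserved). Sites
    with an unknown ancestral state, or one matching neither allele, are
    dropped with counts recorded in the panel history.
    """
    sites = panel.sites
    anc = sites["ancestral"].to_numpy()
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()

    unknown = (anc == ".") | (anc == "") | pd.isna(anc)
    mismatch = ~unknown & (anc != ref) & (anc != alt)
    keep = ~(unknown | mismatch)
    if mismatch.any():
        logger.warning(
            "polarize: dropping %d sites whose ancestral allele matches "
            "neither ref nor alt", int(mismatch.sum()),
        )
    out = panel.take_sites(keep)
    flip = (out.sites["ancestral"] == out.sites["alt"]).to_numpy()
    block = out.dosage[:, flip]
    called = block != MISSING
    block[called] = 2 - block[called]
    out.dosage[:, flip] = block
    out.coding = "derived"
    out.history.append(
        {
            "stage": "polarize",
            "n_unknown_dropped": int(unknown.sum()),
            "n_mismatch_dropped": int(mismatch.sum()),
            "n_flipped": int(flip.sum()),
        }
    )
    return out
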