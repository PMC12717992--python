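"""EHH/iHS selection scan for doubled-haploid panels.

DH lines are fully homozygous, so a panel of them is a naturally phased set
of haplotypes and extended haplotype homozygosity (EHH) can be computed
without statistical phasing. For a core site and allele, EHH at a flanking
site x is the probability that two randomly drawn carrier haplotypes are
identical at every site from the core through x. iHH integrates EHH over
physical distance; the unstandardized score ln(iHH_ancestral/iHH_derived)
is standardized within derived-allele-frequency bins to give iHS, and
candidate sweeps are the sites with empirical p < 0.05 and |iHS| > 2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel, HaplotypePanel

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05
MAF_MIN = 0.05
MAX_GAP_BP = 200_000
N_STD_BINS = 100


def dh_haplotypes(panel: GenotypePanel, population: str) -> HaplotypePanel:
    """Collapse a DH population's diploid dosages {0,2} to haplotypes {0,1}.

    Heterozygous calls are impossible in true DH lines, so any dosage of 1
    is a hard error. Sites with missing calls in the population are dropped
    (EHH needs complete haplotypes), with the count logged.
    """
    if panel.coding != "derived":
        raise ValueError("panel must be polarized (derived coding) for EHH/iHS")
    idx = panel.samples_of_pop(population)
    d = panel.dosage[idx, :]
    n_het = int((d == 1).sum())
    if n_het:
        raise ValueError(
            f"{n_het} heterozygous calls in DH population {population!r}; "
            "not a doubled-haploid panel"
        )
    complete = ~(d == MISSING).any(axis=0)
    if not complete.all():
        logger.info(
            "dh_haplotypes: dropping %d sites with missing calls",
            int((~complete).sum()),
        )
    H = (d[:, complete] // 2).astype(np.uint8)
    return HaplotypePanel(
        line_ids=[panel.sample_ids[i] for i in idx],
        sites=panel.sites.loc[complete, ["chrom", "pos"]].reset_index(drop=True),
        H=H,
    )


def _homozygosity(groups: np.ndarray, n: int) -> float:
    """Sum of C(size,2) over haplotype groups, over C(n,2)."""
    _, counts = np.unique(groups, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(
    panel: HaplotypePanel,
    core_idx: int,
    core_allele: int,
    direction: str,
    ehh_cutoff: float = EHH_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH curve away from a core site for carriers of ``core_allele``.

    Returns (positions, ehh_values) starting at the core (EHH = 1) and
    walking left or right within the core's chromosome. Haplotype identity
    is tracked incrementally: haplotypes are partitioned into groups
    identical from the core through the current site, and EHH is the pair
    homozygosity of that partition. The walk stops after the first point
    whose EHH falls below ``ehh_cutoff``, or at the chromosome end.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    chrom = panel.sites["chrom"].iloc[core_idx]
    on_chrom = np.flatnonzero((panel.sites["chrom"] == chrom).to_numpy())
    carriers = np.flatnonzero(panel.H[:, core_idx] == core_allele)
    n = carriers.size
    if n < 2:
        raise ValueError("fewer than 2 carriers of the core allele")

    k = int(np.searchsorted(on_chrom, core_idx))
    walk = on_chrom[k + 1 :] if direction == "right" else on_chrom[:k][::-1]

    pos_list = [int(panel.sites["pos"].iloc[core_idx])]
    ehh_list = [1.0]
    groups = np.zeros(n, dtype=np.int64)
    for j in walk:
        key = groups * 2 + panel.H[carriers, j]
        _, groups = np.unique(key, return_inverse=True)
        val = _homozygosity(groups, n)
        pos_list.append(int(panel.sites["pos"].iloc[j]))
        ehh_list.append(val)
        if val < ehh_cutoff:
            break
    return np.asarray(pos_list), np.asarray(ehh_list)


def ihh(
    positions: np.ndarray,
    ehh_values: np.ndarray,
    ehh_cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
) -> float:
    """Trapezoidal integral of an EHH curve over physical distance (bp).

    The curve is truncated at the last point with EHH ≥ ``ehh_cutoff``;
    inter-site gaps wider than ``max_gap`` contribute a capped width.
    """
    positions = np.asarray(positions, float)
    ehh_values = np.asarray(ehh_values, float)
    if positions.size < 2:
        return 0.0
    above = np.flatnonzero(ehh_values >= ehh_cutoff)
    if above.size < 2:
        return 0.0
    last = above[-1]
    widths = np.minimum(np.abs(np.diff(positions[: last + 1])), max_gap)
    heights = (ehh_values[:last] + ehh_values[1 : last + 1]) / 2.0
    return float(np.sum(widths * heights))


def _site_ihh(
    panel: HaplotypePanel,
    core_idx: int,
    allele: int,
    ehh_cutoff: float,
    max_gap: int,
) -> tuple[float, bool]:
    """Two-sided iHH (left + right) and an edge-censoring flag."""
    total = 0.0
    censored = False
    chrom = panel.sites["chrom"].iloc[core_idx]
    on_chrom = np.flatnonzero((panel.sites["chrom"] == chrom).to_numpy())
    for direction in ("left", "right"):
        pos, curve = ehh(panel, core_idx, allele, direction, ehh_cutoff)
        total += ihh(pos, curve, ehh_cutoff, max_gap)
        at_end = (
            (direction == "left" and pos[-1] == panel.sites["pos"].iloc[on_chrom[0]])
            or (direction == "right" and pos[-1] == panel.sites["pos"].iloc[on_chrom[-1]])
        )
        if curve[-1] >= ehh_cutoff and at_end and len(on_chrom) > 1:
            censored = True
    return total, censored


def ihs_scan(
    panel: HaplotypePanel,
    maf_min: float = MAF_MIN,
    ehh_cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
    n_bins: int = N_STD_BINS,
    include_edge_censored: bool = False,
) -> pd.DataFrame:
    """Per-site iHS over all sites with derived frequency in [maf, 1−maf].

    ihs_raw = ln(iHH_ancestral / iHH_derived) using both-direction iHH per
    allele; standardized to ihs_std within ``n_bins`` equal-width derived-
    frequency bins. Edge-censored sites (curve hits a chromosome end while
    still above the cutoff) are excluded from standardization unless
    ``include_edge_censored``.
    """
    daf = panel.derived_freq()
    usable = (daf >= maf_min) & (daf <= 1 - maf_min)
    rows = []
    for j in np.flatnonzero(usable):
        ihh_d, cens_d = _site_ihh(panel, j, 1, ehh_cutoff, max_gap)
        ihh_a, cens_a = _site_ihh(panel, j, 0, ehh_cutoff, max_gap)
        raw = (
            float(np.log(ihh_a / ihh_d))
            if ihh_d > 0 and ihh_a > 0
            else float("nan")
        )
        rows.append(
            {
                "chrom": panel.sites["chrom"].iloc[j],
                "pos": int(panel.sites["pos"].iloc[j]),
                "daf": float(daf[j]),
                "ihh_d": ihh_d,
                "ihh_a": ihh_a,
                "ihs_raw": raw,
                "edge_censored": bool(cens_d or cens_a),
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res.assign(ihs_std=[], emp_p=[], significant=[])

    res["ihs_std"] = np.nan
    in_std = np.isfinite(res["ihs_raw"])
    if not include_edge_censored:
        in_std &= ~res["edge_censored"]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_of = np.clip(np.digitize(res["daf"], edges) - 1, 0, n_bins - 1)
    for b in np.unique(bin_of[in_std]):
        sel = in_std & (bin_of == b)
        vals = res.loc[sel, "ihs_raw"]
        if sel.sum() < 2 or vals.std(ddof=0) == 0:
            logger.warning("ihs_scan: bin %d has <2 usable sites; std undefined", b)
            continue
        res.loc[sel, "ihs_std"] = (vals - vals.mean()) / vals.std(ddof=0)
    return res


def empirical_classify(
    ihs_results: pd.DataFrame, alpha: float = 0.05, z_min: float = 2.0
) -> pd.DataFrame:
    """Empirical p by descending-|iHS| rank and the dual-threshold call.

    emp_p = rank(|ihs_std|)/N with rank 1 the most extreme score (average
    ranks for ties); a site is significant iff emp_p < alpha AND
    |ihs_std| > z_min.
    """
    res = ihs_results.copy()
    defined = np.isfinite(res["ihs_std"].to_numpy(float))
    if not defined.any():
        raise ValueError("no sites with a defined standardized iHS")
    res["emp_p"] = np.nan
    absv = res.loc[defined, "ihs_std"].abs()
    ranks = stats.rankdata(-absv, method="average")
    res.loc[defined, "emp_p"] = ranks / defined.sum()
    res["significant"] = (
        (res["emp_p"] < alpha) & (res["ihs_std"].abs() > z_min)
    ).fillna(False)
    return res


def nearest_gene(sites: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Closest gene per site with signed distance and side.

    ``genes`` uses 1-based inclusive intervals (as produced by
    :func:`landrace_popgen.io_filters.read_genes_bed`). Distance is 0 for a
    site inside a gene; otherwise positive when the gene lies upstream
    (lower coordinates) and negative when downstream. Equidistant ties go
    to the upstream (lower-coordinate) gene. Sites on chromosomes absent
    from the annotation are marked unplaced.
    """
    out = []
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}
    for _, site in sites.iterrows():
        chrom, pos = site["chrom"], int(site["pos"])
        g = by_chrom.get(chrom)
        if g is None:
            out.append({"chrom": chrom, "pos": pos, "gene_id": None,
                        "distance": np.nan, "side": "unplaced"})
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        dist = np.maximum.reduce([starts - pos, pos - ends,
                                  np.zeros_like(starts)])
        best = np.min(dist)
        cand = np.flatnonzero(dist == best)
        pick = cand[np.argmin(starts[cand])]  # tie -> lower-coordinate gene
        if best == 0:
            signed, side = 0, "inside"
        elif pos > ends[pick]:
            signed, side = int(pos - ends[pick]), "upstream"
        else:
            signed, side = -int(starts[pick] - pos), "downstream"
        out.append({"chrom": chrom, "pos": pos,
                    "gene_id": g["gene_id"].iloc[pick],
                    "distance": signed, "side": side})
    return pd.DataFrame(out)
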