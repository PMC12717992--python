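"""Per-population diversity, per-individual inbreeding, and geography.

Expected heterozygosity H_exp = 1 - p^2 - q^2 per biallelic site, averaged
over sites with a NaN-ignoring mean, is the diversity currency; gradients of
H_exp (or any per-population statistic) against great-circle distance from a
hypothesised introduction point are tested with Spearman rank correlation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def expected_heterozygosity(
    panel: GenotypePanel,
    population: str,
    segregating_only: bool = False,
) -> tuple[np.ndarray, float]:
    """Per-site H = 1 − p² − q² within one population, and its mean.

    ``p`` is the sample allele frequency among non-missing calls; sites
    with fewer than 2 called genotypes are NaN and excluded from the mean.
    With ``segregating_only`` the mean is over polymorphic sites only.
    """
    idx = panel.samples_of_pop(population)
    ac, an = panel.allele_counts(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an >= 4, ac / np.maximum(an, 1), np.nan)
    h = 1.0 - p**2 - (1.0 - p) ** 2
    use = h.copy()
    if segregating_only:
        use[(ac == 0) | (ac == an)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = float(np.nanmean(use))
    return h, mean


def inbreeding_f(panel: GenotypePanel, sample: str) -> float:
    """Method-of-moments inbreeding coefficient for one individual.

    F = (O_hom − E_hom) / (N − E_hom) with O_hom the observed homozygous
    count over the sample's non-missing sites and E_hom the expected count
    under Hardy–Weinberg in the sample's population cohort, using the
    small-sample correction E_het(site) = 2pq · n/(n−1) on the cohort's
    called allele number n. NaN when the denominator vanishes.
    """
    i = panel.sample_index(sample)
    cohort = panel.samples_of_pop(panel.pop_of_sample[sample])
    ac, an = panel.allele_counts(cohort)

    called = panel.dosage[i, :] != MISSING
    usable = called & (an >= 2)
    if not usable.any():
        return float("nan")
    p = ac[usable] / an[usable]
    n = an[usable]
    e_het = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    e_hom = float(np.sum(1.0 - e_het))
    o_hom = int(np.sum(np.isin(panel.dosage[i, usable], [0, 2])))
    n_sites = int(usable.sum())
    denom = n_sites - e_hom
    if denom == 0:
        logger.warning("inbreeding_f undefined for %s (no expected het)", sample)
        return float("nan")
    return (o_hom - e_hom) / denom


def inbreeding_table(panel: GenotypePanel) -> pd.DataFrame:
    """Inbreeding F for every sample (vectorised cohort frequencies)."""
    rows = []
    for s in panel.sample_ids:
        rows.append(
            {
                "sample": s,
                "population": panel.pop_of_sample[s],
                "F": inbreeding_f(panel, s),
                "n_sites_used": int((panel.dosage[panel.sample_index(s)] != MISSING).sum()),
            }
        )
    return pd.DataFrame(rows)


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) pairs, mean-radius Earth."""
    for lat, lon in (a, b):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"coordinates out of range: {(lat, lon)}")
    la1, lo1, la2, lo2 = map(np.radians, (a[0], a[1], b[0], b[1]))
    s = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0, 1))))


def distances_from(popmap: pd.DataFrame, entry_population: str) -> pd.Series:
    """Haversine km from every population to the named entry population."""
    pm = popmap.set_index("population")
    if entry_population not in pm.index:
        raise KeyError(f"entry population {entry_population!r} not in popmap")
    origin = (pm.loc[entry_population, "latitude"], pm.loc[entry_population, "longitude"])
    return pd.Series(
        {
            p: haversine_km(origin, (row["latitude"], row["longitude"]))
            for p, row in pm.iterrows()
        },
        name=f"distance_from_{entry_population}_km",
    )


def gradient_correlation(
    values_by_pop: "pd.Series | dict",
    entry_population: str,
    popmap: pd.DataFrame,
    subset: list[str] | None = None,
) -> tuple[float, float]:
    """Spearman ρ (and two-sided p) of a per-population statistic against
    haversine distance from an entry population.

    ``subset`` restricts to a population list (e.g. one geographic
    cluster). Returns (nan, nan) when either vector is constant.
    """
    values = pd.Series(values_by_pop)
    dist = distances_from(popmap, entry_population)
    pops = [p for p in values.index if p in dist.index]
    if subset is not None:
        pops = [p for p in pops if p in set(subset)]
    if len(pops) < 4:
        raise ValueError(f"need >= 4 populations with values, got {len(pops)}")
    x = dist.loc[pops].to_numpy(float)
    y = values.loc[pops].to_numpy(float)
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        logger.warning("gradient_correlation: constant input, rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y, nan_policy="omit")
    return float(rho), float(p)


def diversity_table(
    panel: GenotypePanel,
    popmap: pd.DataFrame,
    entry_south: str,
    entry_north: str,
) -> pd.DataFrame:
    """Per-population mean H_exp plus distances to the two entry points."""
    d_s = distances_from(popmap, entry_south)
    d_n = distances_from(popmap, entry_north)
    rows = []
    for pop in panel.populations:
        h, mean = expected_heterozygosity(panel, pop)
        rows.append(
            {
                "population": pop,
                "mean_hexp": mean,
                "n_sites_used": int(np.isfinite(h).sum()),
                "distance_south_km": float(d_s.get(pop, np.nan)),
                "distance_north_km": float(d_n.get(pop, np.nan)),
            }
        )
    return pd.DataFrame(rows)
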