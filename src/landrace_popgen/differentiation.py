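"""Pairwise Hudson F_ST, Slatkin linearization, and distance-matrix tests.

The F_ST estimator is the Hudson estimator in the Bhatia et al.
parameterisation: per-site numerator and denominator are combined as a
ratio of sums ("ratio of averages"), with a delete-one-block jackknife over
contiguous variant blocks for the standard error. Isolation by distance is
assessed as the Spearman correlation of pairwise F_ST with geographic
(haversine) or environmental (scaled-Euclidean bioclim) distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .diversity import haversine_km
from .panel import GenotypePanel

logger = logging.getLogger(__name__)


def hudson_components(p1, n1, p2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson F_ST numerator and denominator.

    ``p1, p2`` are sample allele frequencies and ``n1, n2`` the called
    (haploid) allele counts in each population. Sites with n < 2 in either
    population are returned as NaN and should be skipped by the caller.

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def blockwise_fst(
    nums: np.ndarray, dens: np.ndarray, block_size: int = 100_000
) -> tuple[float, float]:
    """Overall F_ST as a ratio of sums, with block-jackknife standard error.

    Sites are grouped into contiguous blocks of ``block_size`` variants;
    the SE is the delete-one-block jackknife of the ratio-of-sums
    estimator. A single usable block yields a finite F_ST but NaN SE.
    """
    nums = np.asarray(nums, float)
    dens = np.asarray(dens, float)
    ok = np.isfinite(nums) & np.isfinite(dens)
    nums, dens = nums[ok], dens[ok]
    if nums.size == 0:
        raise ValueError("no usable sites")
    tot_n, tot_d = nums.sum(), dens.sum()
    if tot_d == 0:
        logger.warning("blockwise_fst: zero denominator, F_ST undefined")
        return float("nan"), float("nan")
    fst = tot_n / tot_d

    n_blocks = int(np.ceil(nums.size / block_size))
    if n_blocks < 2:
        return float(fst), float("nan")
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        d = tot_d - dens[sl].sum()
        loo[b] = (tot_n - nums[sl].sum()) / d if d != 0 else np.nan
    loo = loo[np.isfinite(loo)]
    if loo.size < 2:
        return float(fst), float("nan")
    m = loo.mean()
    se = np.sqrt((loo.size - 1) / loo.size * np.sum((loo - m) ** 2))
    return float(fst), float(se)


def slatkin_linearized(fst: float) -> float:
    """Slatkin's linearized F_ST, F/(1−F); NaN (with warning) at F=1."""
    if fst == 1:
        logger.warning("slatkin_linearized: F_ST = 1, value infinite")
        return float("nan")
    return fst / (1.0 - fst)


@dataclass
class FstMatrix:
    """Pairwise differentiation with companion distance matrices."""

    populations: list[str]
    fst: np.ndarray
    linearized: np.ndarray
    se: np.ndarray
    n_sites: np.ndarray
    geo_km: np.ndarray | None = None
    env_dist: np.ndarray | None = None
    clusters: dict[str, str] = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        rows = []
        k = len(self.populations)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "popA": self.populations[i],
                        "popB": self.populations[j],
                        "fst": self.fst[i, j],
                        "fst_floored": max(self.fst[i, j], 0.0),
                        "linearized": self.linearized[i, j],
                        "se": self.se[i, j],
                        "n_sites": int(self.n_sites[i, j]),
                        "geo_km": (
                            self.geo_km[i, j] if self.geo_km is not None else np.nan
                        ),
                        "env_dist": (
                            self.env_dist[i, j]
                            if self.env_dist is not None
                            else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


def pairwise_fst(
    panel: GenotypePanel,
    block_size: int = 100_000,
    seg_scope: str = "pair",
    popmap: pd.DataFrame | None = None,
    bioclim: pd.DataFrame | None = None,
) -> FstMatrix:
    """All-pairs Hudson F_ST over the panel's populations.

    ``seg_scope`` selects the sites entering each pair: ``"pair"`` keeps
    sites segregating in the union of the two populations (default);
    ``"global"`` keeps sites segregating anywhere in the panel.
    """
    if seg_scope not in ("pair", "global"):
        raise ValueError("seg_scope must be 'pair' or 'global'")
    pops = panel.populations
    k = len(pops)
    counts = {}
    for pop in pops:
        idx = panel.samples_of_pop(pop)
        counts[pop] = panel.allele_counts(idx)

    if seg_scope == "global":
        ac, an = panel.allele_counts()
        global_seg = (ac > 0) & (ac < an)

    fst = np.zeros((k, k))
    lin = np.zeros((k, k))
    se = np.full((k, k), np.nan)
    nsites = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            ac1, an1 = counts[pops[i]]
            ac2, an2 = counts[pops[j]]
            if seg_scope == "pair":
                acu, anu = ac1 + ac2, an1 + an2
                seg = (acu > 0) & (acu < anu)
            else:
                seg = global_seg
            with np.errstate(invalid="ignore", divide="ignore"):
                p1 = ac1 / np.maximum(an1, 1)
                p2 = ac2 / np.maximum(an2, 1)
            num, den = hudson_components(p1[seg], an1[seg], p2[seg], an2[seg])
            f, s = blockwise_fst(num, den, block_size)
            fst[i, j] = fst[j, i] = f
            lin[i, j] = lin[j, i] = slatkin_linearized(f)
            se[i, j] = se[j, i] = s
            nsites[i, j] = nsites[j, i] = int(
                (np.isfinite(num) & np.isfinite(den)).sum()
            )

    geo = None
    clusters: dict[str, str] = {}
    if popmap is not None:
        pm = popmap.set_index("population")
        geo = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                a = (pm.loc[pops[i], "latitude"], pm.loc[pops[i], "longitude"])
                b = (pm.loc[pops[j], "latitude"], pm.loc[pops[j], "longitude"])
                geo[i, j] = geo[j, i] = haversine_km(a, b)
        if "cluster" in pm.columns:
            clusters = {p: pm.loc[p, "cluster"] for p in pops if p in pm.index}

    env = None
    if bioclim is not None:
        env_full = environmental_distance(bioclim)
        order = [list(bioclim["population"]).index(p) for p in pops]
        env = env_full[np.ix_(order, order)]

    return FstMatrix(
        populations=pops, fst=fst, linearized=lin, se=se, n_sites=nsites,
        geo_km=geo, env_dist=env, clusters=clusters,
    )


def environmental_distance(bioclim: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distance on standardized bioclim variables.

    Each variable is centered and scaled to exactly unit standard
    deviation across populations; missing cells are mean-imputed (which
    after centering is zero). Zero-variance variables are dropped with a
    warning.
    """
    var_cols = [c for c in bioclim.columns
                if c not in ("population", "latitude", "longitude")]
    X = bioclim[var_cols].to_numpy(float)
    col_mean = np.nanmean(X, axis=0)
    nan_cells = int(np.isnan(X).sum())
    if nan_cells:
        logger.info("environmental_distance: mean-imputing %d cells", nan_cells)
        X = np.where(np.isnan(X), col_mean, X)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "environmental_distance: dropping zero-variance variables %s",
            [v for v, k in zip(var_cols, keep) if not k],
        )
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return squareform(pdist(X, metric="euclidean"))


def _pair_subset_mask(pops: list[str], clusters: dict[str, str], subset: str):
    k = len(pops)
    mask = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            if subset == "all":
                mask[i, j] = True
            else:
                same = clusters.get(pops[i]) == clusters.get(pops[j])
                mask[i, j] = same if subset == "within-cluster" else not same
    return mask


def ibd_test(
    fst_values: np.ndarray,
    dist_values: np.ndarray,
    populations: list[str] | None = None,
    clusters: dict[str, str] | None = None,
    subset: str = "all",
) -> tuple[float, float]:
    """Spearman test of isolation by distance over upper-triangle pairs.

    ``subset`` is one of {"all", "within-cluster", "between-cluster"};
    cluster subsets need ``populations`` and ``clusters``. Note the pairs
    are not independent, so the p-value is the plain Spearman one the
    analysis convention uses, not a Mantel permutation p.
    """
    fst_values = np.asarray(fst_values, float)
    dist_values = np.asarray(dist_values, float)
    if fst_values.shape != dist_values.shape:
        raise ValueError("matrices not conformable")
    if subset == "all":
        iu = np.triu_indices(fst_values.shape[0], k=1)
        x, y = fst_values[iu], dist_values[iu]
    else:
        if populations is None or clusters is None:
            raise ValueError("cluster subsets need populations and clusters")
        mask = _pair_subset_mask(populations, clusters, subset)
        x, y = fst_values[mask], dist_values[mask]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable pairs")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def mantel_test(
    fst_values: np.ndarray,
    dist_values: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel permutation alternative to :func:`ibd_test` (rows/cols
    permuted jointly); provided because pairwise values are not
    independent."""
    rng = np.random.default_rng(seed)
    k = fst_values.shape[0]
    iu = np.triu_indices(k, k=1)
    obs, _ = stats.spearmanr(fst_values[iu], dist_values[iu])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        r, _ = stats.spearmanr(fst_values[np.ix_(perm, perm)][iu], dist_values[iu])
        if abs(r) >= abs(obs):
            count += 1
    logger.info("mantel_test used (n_perm=%d)", n_perm)
    return float(obs), (count + 1) / (n_perm + 1)


def cluster_contrast(
    fst_values: np.ndarray,
    populations: list[str],
    clusters: dict[str, str],
) -> dict:
    """Kolmogorov–Smirnov comparison of within- vs between-cluster F_ST."""
    sizes = pd.Series(list(clusters.values())).value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ValueError(
            f"cluster(s) with < 2 populations (empty within set): "
            f"{list(small.index)}"
        )
    within_mask = _pair_subset_mask(populations, clusters, "within-cluster")
    between_mask = _pair_subset_mask(populations, clusters, "between-cluster")
    within = fst_values[within_mask]
    between = fst_values[between_mask]
    if within.size == 0 or between.size == 0:
        raise ValueError("need non-empty within- and between-cluster pair sets")
    ks = stats.ks_2samp(within, between)
    return {
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
        "within_mean": float(within.mean()),
        "within_median": float(np.median(within)),
        "between_mean": float(between.mean()),
        "between_median": float(np.median(between)),
    }
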