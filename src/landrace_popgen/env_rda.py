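"""Climate characterization and redundancy-analysis variance partitioning.

Redundancy analysis (RDA) regresses a multivariate genotype response on
predictor blocks; a *partial* RDA first removes conditioning blocks from
both sides by ordinary least squares. Explained variance is summarized by
the Ezekiel-adjusted R² and a permutation p-value (rows of the predictor
residuals permuted). Climate predictors enter through a forward selection
with the classic double stopping rule (candidate permutation p and the
global-model adjusted R² ceiling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import gradient_correlation
from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

BIOCLIM_VARS = [f"bio{i}" for i in range(1, 20)]


# ---------------------------------------------------------------------------
# response construction
# ---------------------------------------------------------------------------

def genotype_response(panel: GenotypePanel, level: str = "individual") -> np.ndarray:
    """Centered, mean-imputed dosage matrix as the RDA response.

    ``level="individual"`` returns one row per sample;
    ``level="population"`` one row of allele frequencies per population.
    """
    if level == "individual":
        X = panel.dosage.astype(float)
        X[panel.dosage == MISSING] = np.nan
    elif level == "population":
        X = np.vstack([panel.allele_freq(panel.samples_of_pop(p))
                       for p in panel.populations])
    else:
        raise ValueError("level must be 'individual' or 'population'")
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(X), col_mean, X)
    return X - X.mean(axis=0)


def neutral_pcs(
    panel: GenotypePanel, fourfold_sites: pd.DataFrame, n_pcs: int = 2
) -> np.ndarray:
    """Principal-component scores of individuals at putatively neutral sites.

    The panel is restricted to the provided (chrom, pos) list of 4-fold
    degenerate sites, mean-imputed, centered, and decomposed by SVD; the
    first ``n_pcs`` score vectors are returned (n_samples x n_pcs).
    """
    key = panel.sites[["chrom", "pos"]].astype({"chrom": str})
    target = fourfold_sites[["chrom", "pos"]].astype({"chrom": str})
    mask = key.merge(target, how="left", indicator=True)["_merge"] == "both"
    mask = mask.to_numpy()
    if not mask.any():
        raise ValueError("no overlap between fourfold site list and panel")
    if panel.n_samples < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 individuals")
    X = genotype_response(panel.take_sites(mask))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("zero genetic variance at neutral sites")
    return U[:, :n_pcs] * s[:n_pcs]


# ---------------------------------------------------------------------------
# partial RDA core
# ---------------------------------------------------------------------------

def _as_matrix(M) -> np.ndarray:
    M = np.asarray(M, float)
    return M[:, None] if M.ndim == 1 else M


def _residualize(M: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """OLS residuals of M on [1, Z] (intercept always included)."""
    n = M.shape[0]
    D = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ beta


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    return U[:, :rank]


def partial_rda(
    response,
    predictors,
    conditions=None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Constrained-ordination fit of ``response`` on ``predictors`` given
    ``conditions``.

    Both response and predictors are residualized on the conditions; the
    constrained variance is the squared norm of the projection of the
    response residuals onto the predictor-residual column space. Returns
    r2, Ezekiel-adjusted r2, rank used, and a permutation p-value obtained
    by freely permuting rows of the predictor residuals (p = (1+k)/(1+B)).
    """
    Y = _as_matrix(response)
    X = _as_matrix(predictors)
    Z = _as_matrix(conditions) if conditions is not None else None
    if Z is not None and Z.shape[1] == 0:
        Z = None
    n = Y.shape[0]
    if X.shape[0] != n or (Z is not None and Z.shape[0] != n):
        raise ValueError("row mismatch between response/predictors/conditions")

    Yr = _residualize(Y, Z)
    Xr = _residualize(X, Z)
    ss_tot = float((Yr**2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance after conditioning")
    Q = _orthonormal_basis(Xr)
    m = Q.shape[1]
    if m < X.shape[1]:
        logger.info("partial_rda: predictors rank-deficient, rank %d used", m)

    def _r2(Xmat):
        B = _orthonormal_basis(Xmat)
        if B.shape[1] == 0:
            return 0.0
        return float(((B.T @ Yr) ** 2).sum()) / ss_tot

    r2 = _r2(Xr)
    adj = np.nan
    if n - 1 - m > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _r2(Xr[perm]) >= r2:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return {"r2": r2, "adj_r2": float(adj), "rank": m, "p": float(p), "n": n}


# ---------------------------------------------------------------------------
# forward selection and the four-model comparison
# ---------------------------------------------------------------------------

def forward_select(
    response,
    bioclim_vars: pd.DataFrame,
    stop_r2: float | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    collinear_r2: float = 0.99,
) -> pd.DataFrame:
    """Greedy forward selection of bioclim predictors for the RDA.

    At each step the candidate giving the largest cumulative adjusted R²
    is considered; it is admitted only if its marginal permutation p
    (tested conditional on the already-selected set) is below ``alpha``.
    Selection ends when no candidate passes, or once the cumulative
    adjusted R² reaches ``stop_r2`` (default: the adjusted R² of the model
    with every candidate) — the double stopping rule, with the
    ceiling-reaching variable retained since it passed its own test.
    Candidates nearly collinear with the selected set are skipped with a
    warning.
    """
    Y = _as_matrix(response)
    cols = list(bioclim_vars.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 candidate variables")
    X_all = bioclim_vars.to_numpy(float)
    if stop_r2 is None:
        stop_r2 = partial_rda(Y, X_all, n_perm=0, seed=seed)["adj_r2"]

    selected: list[str] = []
    steps = []
    rng = np.random.default_rng(seed)
    while True:
        best = None
        for v in cols:
            if v in selected:
                continue
            xv = bioclim_vars[v].to_numpy(float)[:, None]
            if selected:
                S = bioclim_vars[selected].to_numpy(float)
                res = _residualize(xv, S)
                denom = float(((xv - xv.mean()) ** 2).sum())
                if denom == 0 or 1 - float((res**2).sum()) / denom >= collinear_r2:
                    logger.warning("forward_select: %s collinear with selected, skipped", v)
                    continue
            cand_cols = selected + [v]
            fit = partial_rda(
                Y, bioclim_vars[cand_cols].to_numpy(float), n_perm=0, seed=0
            )
            # strict improvement beyond float noise: ties go to the
            # earlier-listed variable, keeping selection deterministic
            if best is None or fit["adj_r2"] > best[1] + 1e-9:
                best = (v, fit["adj_r2"])
        if best is None:
            break
        v, cand_adj = best
        marg = partial_rda(
            Y,
            bioclim_vars[v].to_numpy(float),
            conditions=(
                bioclim_vars[selected].to_numpy(float) if selected else None
            ),
            n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        if marg["p"] >= alpha:
            break
        selected.append(v)
        steps.append(
            {"variable": v, "cum_adj_r2": cand_adj, "perm_p": marg["p"],
             "step": len(selected)}
        )
        # reaching the global-model ceiling means selection is complete;
        # the admitting variable passed its permutation test, so it stays
        if cand_adj > stop_r2 + 1e-12:
            break
    return pd.DataFrame(steps, columns=["step", "variable", "cum_adj_r2", "perm_p"])


@dataclass
class RdaReport:
    selected: pd.DataFrame
    models: pd.DataFrame
    best_model: str


def variance_partition(
    response,
    climate_vars,
    neutral_pc_scores,
    lat_lon,
    n_perm: int = 999,
    seed: int = 0,
) -> RdaReport:
    """Four-model comparison of climate, neutral structure, and geography.

    Fits the full model (all three blocks as predictors) and the three
    "pure" models in which one block is the predictor and the other two
    are conditions; models are ranked by adjusted R².
    """
    blocks = {
        "climate": _as_matrix(climate_vars),
        "structure": _as_matrix(neutral_pc_scores),
        "geography": _as_matrix(lat_lon),
    }
    for name, B in blocks.items():
        if np.allclose(B.std(axis=0), 0):
            raise ValueError(f"block {name!r} is constant")
    Y = _as_matrix(response)
    rng = np.random.default_rng(seed)

    rows = []
    full_X = np.column_stack(list(blocks.values()))
    fit = partial_rda(Y, full_X, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
    rows.append({"model": "full", **{k: fit[k] for k in ("r2", "adj_r2", "p", "rank")}})
    for name in blocks:
        others = np.column_stack([blocks[o] for o in blocks if o != name])
        fit = partial_rda(
            Y, blocks[name], conditions=others,
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        )
        rows.append(
            {"model": f"{name}-pure", **{k: fit[k] for k in ("r2", "adj_r2", "p", "rank")}}
        )
    models = pd.DataFrame(rows)
    best = models.loc[models["adj_r2"].idxmax(), "model"]
    return RdaReport(selected=pd.DataFrame(), models=models, best_model=str(best))


# ---------------------------------------------------------------------------
# climate characterization
# ---------------------------------------------------------------------------

def route_correlation(
    bioclim: pd.DataFrame,
    variable: str,
    entry_population: str,
    popmap: pd.DataFrame,
    subset: list[str] | None = None,
) -> tuple[float, float]:
    """Spearman ρ of one bioclim variable against distance from an entry
    point, optionally within a population subset (a cluster)."""
    values = bioclim.set_index("population")[variable]
    return gradient_correlation(values, entry_population, popmap, subset)


def cluster_bioclim_tests(
    bioclim: pd.DataFrame,
    cluster_of_pop: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of each bioclim variable between
    the two clusters; reports the per-variable statistic and p."""
    labels = bioclim["population"].map(cluster_of_pop)
    groups = [g for g in labels.dropna().unique()]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {groups}")
    rows = []
    for v in [c for c in bioclim.columns if c.startswith("bio")]:
        a = bioclim.loc[labels == groups[0], v].dropna()
        b = bioclim.loc[labels == groups[1], v].dropna()
        if a.empty or b.empty:
            raise ValueError(f"empty cluster for variable {v}")
        if np.std(np.concatenate([a, b])) == 0:
            logger.warning("cluster_bioclim_tests: %s all tied, p = 1", v)
            stat, p = 0.0, 1.0
        else:
            u = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(u.statistic), float(u.pvalue)
        rows.append({"variable": v, "statistic": stat, "p": p,
                     "significant": p < alpha})
    df = pd.DataFrame(rows)
    logger.info(
        "cluster_bioclim_tests: %d/%d variables significant at %.3g",
        int(df["significant"].sum()), len(df), alpha,
    )
    return df
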