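"""GERP-based genetic load accounting.

Each derived allele at a site carrying a GERP (rejected-substitutions)
score contributes that score to an individual's load; the per-individual
total is the dot product of the GERP vector with the derived-dosage vector.
Within a group of samples, load splits into a fixed component (sites where
the derived allele is fixed in the group, counted as 2 x GERP) and a
segregating component (the remaining polymorphic sites, dosage-weighted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import distances_from
from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


def exclude_high_missing(
    panel: GenotypePanel, quantile: float = 0.95
) -> tuple[GenotypePanel, list[str], float]:
    """Drop samples whose missing fraction exceeds the empirical quantile.

    The threshold is the ``quantile`` of the per-sample missing-fraction
    distribution; exclusion is by strict ``>``, so with no missing data
    anywhere nobody is excluded. Returns (panel, excluded ids, threshold).
    """
    frac = panel.sample_missing_fraction()
    threshold = float(np.quantile(frac, quantile))
    excluded = [s for s, f in zip(panel.sample_ids, frac) if f > threshold]
    keep = [s for s in panel.sample_ids if s not in set(excluded)]
    logger.info(
        "exclude_high_missing: threshold %.4g (%.2f%% missing), %d excluded",
        threshold, 100 * threshold, len(excluded),
    )
    return panel.take_samples(keep), excluded, threshold


def _gerp_vector(panel: GenotypePanel, gerp: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(scores aligned to panel sites, boolean scored mask); strict
    (chrom, pos) join."""
    key = panel.sites[["chrom", "pos"]].astype({"chrom": str})
    merged = key.merge(
        gerp.astype({"chrom": str}), on=["chrom", "pos"], how="left"
    )
    scores = merged["gerp_score"].to_numpy(float)
    scored = np.isfinite(scores)
    if not scored.any():
        raise ValueError("no (chrom,pos) overlap between panel and GERP track")
    n_skip = int((~scored).sum())
    if n_skip:
        logger.info("load: %d panel sites without a GERP score skipped", n_skip)
    return np.where(scored, scores, 0.0), scored


def _derived_dosage(panel: GenotypePanel) -> np.ndarray:
    if panel.coding != "derived":
        raise ValueError("panel must be polarized to derived coding for load")
    d = panel.dosage.astype(float)
    d[panel.dosage == MISSING] = 0.0  # missing cells contribute no load
    return d


def individual_load(
    panel: GenotypePanel, gerp: pd.DataFrame, presence_only: bool = False
) -> pd.Series:
    """Per-sample total load Σ GERP × derived dosage (MISSING skipped).

    With ``presence_only`` each site's GERP counts once whenever the
    sample carries any derived allele there (a sensitivity mode).
    """
    scores, _ = _gerp_vector(panel, gerp)
    d = _derived_dosage(panel)
    if presence_only:
        d = (d > 0).astype(float)
    return pd.Series(d @ scores, index=panel.sample_ids, name="total_load")


def high_deleterious_count(
    panel: GenotypePanel, gerp: pd.DataFrame, threshold: float = 5.0
) -> pd.Series:
    """Derived-allele count at sites with GERP strictly above ``threshold``."""
    scores, scored = _gerp_vector(panel, gerp)
    high = scored & (scores > threshold)
    d = _derived_dosage(panel)
    return pd.Series(
        d[:, high].sum(axis=1).astype(int),
        index=panel.sample_ids,
        name="high_del_count",
    )


@dataclass
class GroupLoad:
    group: str
    fixed_load: float
    n_fixed_sites: int
    n_seg_sites: int
    n_ancestral_fixed: int
    n_unclassified: int


def partition_load(
    panel: GenotypePanel,
    gerp: pd.DataFrame,
    group_of_sample: dict[str, str],
) -> tuple[dict[str, GroupLoad], pd.Series]:
    """Fixed vs segregating load per group.

    Within each group, sites are classified on non-missing calls as
    derived-fixed (frequency 1), ancestral-fixed (0) or segregating; the
    classification is group-relative. fixed_load = Σ 2·GERP over
    derived-fixed sites; seg_load(sample) = Σ GERP·dosage over the
    group's segregating sites.
    """
    scores, scored = _gerp_vector(panel, gerp)
    d = _derived_dosage(panel)
    groups: dict[str, GroupLoad] = {}
    seg_load = pd.Series(0.0, index=panel.sample_ids, name="seg_load")
    for group in dict.fromkeys(group_of_sample.values()):
        idx = [i for i, s in enumerate(panel.sample_ids)
               if group_of_sample.get(s) == group]
        if len(idx) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        ac, an = panel.allele_counts(idx)
        unclass = an == 0
        if unclass.any():
            logger.info(
                "partition_load: %d sites all-missing in %s left unclassified",
                int(unclass.sum()), group,
            )
        derived_fixed = scored & (an > 0) & (ac == an)
        anc_fixed = scored & (an > 0) & (ac == 0)
        seg = scored & (an > 0) & (ac > 0) & (ac < an)
        groups[group] = GroupLoad(
            group=group,
            fixed_load=float(2.0 * scores[derived_fixed].sum()),
            n_fixed_sites=int(derived_fixed.sum()),
            n_seg_sites=int(seg.sum()),
            n_ancestral_fixed=int(anc_fixed.sum()),
            n_unclassified=int((scored & unclass).sum()),
        )
        for i in idx:
            seg_load.iloc[i] = float(d[i, seg] @ scores[seg])
    return groups, seg_load


def load_table(
    panel: GenotypePanel,
    gerp: pd.DataFrame,
    group_of_sample: dict[str, str] | None = None,
    high_del_threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-sample load summary (total, high-deleterious count, missing
    fraction, and — when groups are given — the segregating component)."""
    tab = pd.DataFrame(
        {
            "sample": panel.sample_ids,
            "population": [panel.pop_of_sample[s] for s in panel.sample_ids],
            "total_load": individual_load(panel, gerp).to_numpy(),
            "high_del_count": high_deleterious_count(
                panel, gerp, high_del_threshold
            ).to_numpy(),
            "missing_frac": panel.sample_missing_fraction(),
        }
    )
    if group_of_sample is not None:
        tab["group"] = tab["sample"].map(group_of_sample)
        _, seg = partition_load(panel, gerp, group_of_sample)
        tab["seg_load"] = seg.to_numpy()
    return tab


def load_correlates(
    load_tab: pd.DataFrame,
    popmap: pd.DataFrame,
    entry_points: list[str],
    bioclim: pd.DataFrame | None = None,
    bioclim_vars: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlations of individual load with route distance and
    climate, plus pairwise group KS contrasts when groups are present."""
    rows = []
    for entry in entry_points:
        dist = distances_from(popmap, entry)
        x = load_tab["population"].map(dist).to_numpy(float)
        y = load_tab["total_load"].to_numpy(float)
        if np.nanstd(y) == 0 or np.nanstd(x) == 0:
            logger.warning("load_correlates: constant input for %s", entry)
            rows.append({"pairing": f"load~distance_{entry}",
                         "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(x, y, nan_policy="omit")
        rows.append({"pairing": f"load~distance_{entry}", "rho": float(rho),
                     "p": float(p)})
    if bioclim is not None:
        variables = bioclim_vars or [c for c in bioclim.columns
                                     if c.startswith("bio")]
        bc = bioclim.set_index("population")
        for v in variables:
            x = load_tab["population"].map(bc[v]).to_numpy(float)
            y = load_tab["total_load"].to_numpy(float)
            if np.nanstd(x) == 0 or np.nanstd(y) == 0:
                rows.append({"pairing": f"load~{v}", "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(x, y, nan_policy="omit")
            rows.append({"pairing": f"load~{v}", "rho": float(rho), "p": float(p)})
    if "group" in load_tab.columns:
        groups = [g for g in load_tab["group"].dropna().unique()]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = load_tab.loc[load_tab["group"] == groups[i], "total_load"]
                b = load_tab.loc[load_tab["group"] == groups[j], "total_load"]
                ks = stats.ks_2samp(a, b)
                rows.append(
                    {
                        "pairing": f"ks:{groups[i]}|{groups[j]}",
                        "rho": float(ks.statistic),
                        "p": float(ks.pvalue),
                    }
                )
    return pd.DataFrame(rows)
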