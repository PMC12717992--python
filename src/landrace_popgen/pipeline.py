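"""Config-driven orchestration of the full analysis.

A run config (YAML or dict) either names real input files (VCF, popmap,
coordinates, GERP, bioclim, genes BED, 4-fold site list) or carries a
``simulate`` block, in which case the synthetic bundle is generated first
and then consumed through exactly the same file-based path. Stages execute
in order filter → diversity → fst → ihs → rda → load; each writes TSVs
under the output directory and appends provenance (parameters, input
hashes, seed) to a machine-readable run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import differentiation as diff
from . import env_rda
from . import io_filters
from . import load_calc
from . import sweep_scan
from . import synthetic_data as synth

logger = logging.getLogger(__name__)

STAGES = ("filter", "diversity", "fst", "ihs", "rda", "load")

INPUT_KEYS = ("vcf", "popmap", "coords", "gerp", "bioclim", "genes", "fourfold")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate(config: dict) -> list[str]:
    """Cheap cross-file consistency checks; returns a list of problems."""
    problems = []
    inputs = config.get("inputs", {})
    simulate = config.get("simulate")
    if not inputs and simulate is None:
        problems.append("neither inputs nor a simulate block present")
        return problems
    if simulate is not None:
        return problems  # the generator emits a consistent bundle
    for key in ("vcf", "popmap"):
        if key not in inputs:
            problems.append(f"missing required input {key!r}")
    if problems:
        return problems
    try:
        popmap = io_filters.read_popmap(inputs["popmap"])
    except ValueError as e:
        return [str(e)]
    from cyvcf2 import VCF

    vcf_samples = set(VCF(str(inputs["vcf"])).samples)
    mapped = set(popmap["sample"])
    for s in sorted(vcf_samples - mapped):
        problems.append(f"VCF sample {s!r} absent from popmap")
    pops = set(popmap["population"])
    for key in ("coords", "bioclim"):
        if key in inputs:
            try:
                tab = pd.read_csv(inputs[key], sep="\t")
            except Exception as e:  # malformed file is itself a problem
                problems.append(f"{key}: unreadable ({e})")
                continue
            missing = pops - set(tab.get("population", []))
            for p in sorted(missing):
                problems.append(f"{key}: population {p!r} missing")
    if "gerp" in inputs:
        try:
            gerp = io_filters.read_gerp(inputs["gerp"])
            vcf_sites = sum(1 for _ in VCF(str(inputs["vcf"])))
            frac = min(len(gerp) / max(vcf_sites, 1), 1.0)
            logger.info("validate: GERP covers <= %.1f%% of VCF sites", 100 * frac)
        except ValueError as e:
            problems.append(str(e))
    return problems


def run(config: dict, out_dir) -> dict:
    """Execute the enabled stages; returns the run report (also written
    to ``report.json``). A failing stage halts its dependents but already
    written outputs persist."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    params = config.get("params", {})
    report: dict = {"seed": seed, "config": _jsonable(config), "stages": {}}

    sim_cfg = None
    if config.get("simulate") is not None:
        sim_block = dict(config["simulate"])
        sweeps = [synth.SweepSpec(**s) for s in sim_block.pop("sweep_specs", [])]
        sim_cfg = synth.SimConfig(seed=seed, sweep_specs=sweeps, **sim_block)
        inputs = synth.write_bundle(sim_cfg, out / "sim")
    else:
        inputs = dict(config["inputs"])

    problems = validate({"inputs": inputs})
    if problems:
        raise ValueError("pre-flight validation failed: " + "; ".join(problems))
    report["inputs"] = {k: {"path": str(v), "sha256": _sha256(v)}
                       for k, v in inputs.items() if Path(v).exists()}

    popmap = io_filters.read_coordinates(inputs["coords"]) if "coords" in inputs else None
    gerp = io_filters.read_gerp(inputs["gerp"]) if "gerp" in inputs else None
    bioclim = io_filters.read_bioclim(inputs["bioclim"]) if "bioclim" in inputs else None
    entry_south = config.get("entry_south") or (
        popmap["population"].iloc[0] if popmap is not None else None
    )
    entry_north = config.get("entry_north") or (
        popmap["population"].iloc[1] if popmap is not None else None
    )

    panel = None
    polarized = None
    try:
        # ---- filter ---------------------------------------------------
        panel = io_filters.read_genotypes(inputs["vcf"], inputs["popmap"])
        if "filter" in stages:
            p = params.get("filter", {})
            panel = io_filters.filter_sites(
                panel,
                quality_whitelist=tuple(
                    p.get("quality_whitelist", io_filters.DEFAULT_QUALITY_WHITELIST)
                ),
                max_site_missing=p.get("max_site_missing", 1.0),
                drop_monomorphic=p.get("drop_monomorphic", False),
            )
            report["stages"]["filter"] = {"status": "ok",
                                          "history": panel.history}
        polarized = io_filters.polarize_to_ancestral(panel)

        # ---- diversity ------------------------------------------------
        if "diversity" in stages and popmap is not None:
            tab = div.diversity_table(panel, popmap, entry_south, entry_north)
            tab.to_csv(out / "diversity.tsv", sep="\t", index=False)
            inb = div.inbreeding_table(panel)
            inb.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
            hexp = tab.set_index("population")["mean_hexp"]
            rho_s, p_s = div.gradient_correlation(hexp, entry_south, popmap)
            rho_n, p_n = div.gradient_correlation(hexp, entry_north, popmap)
            report["stages"]["diversity"] = {
                "status": "ok",
                "outputs": ["diversity.tsv", "inbreeding.tsv"],
                "hexp_vs_south": {"rho": rho_s, "p": p_s},
                "hexp_vs_north": {"rho": rho_n, "p": p_n},
            }

        # ---- fst ------------------------------------------------------
        if "fst" in stages:
            p = params.get("fst", {})
            fm = diff.pairwise_fst(
                panel,
                block_size=p.get("block_size", 100_000),
                seg_scope=p.get("seg_scope", "pair"),
                popmap=popmap,
                bioclim=bioclim,
            )
            fm.to_long().to_csv(out / "fst_long.tsv", sep="\t", index=False)
            pd.DataFrame(fm.fst, index=fm.populations, columns=fm.populations
                         ).to_csv(out / "fst_matrix.tsv", sep="\t")
            stage = {"status": "ok",
                     "outputs": ["fst_long.tsv", "fst_matrix.tsv"]}
            if fm.geo_km is not None:
                rho, pv = diff.ibd_test(fm.fst, fm.geo_km)
                stage["ibd_geo"] = {"rho": rho, "p": pv}
            if fm.env_dist is not None:
                rho, pv = diff.ibd_test(fm.fst, fm.env_dist)
                stage["ibd_env"] = {"rho": rho, "p": pv}
            if fm.clusters:
                stage["cluster_contrast"] = diff.cluster_contrast(
                    fm.fst, fm.populations, fm.clusters
                )
            report["stages"]["fst"] = stage

        # ---- ihs ------------------------------------------------------
        if "ihs" in stages:
            p = params.get("ihs", {})
            hap = None
            if sim_cfg is not None:
                # DH library drawn from the focal population's simulated
                # frequencies, with the configured sweeps planted
                focal = p.get("population") or (
                    sim_cfg.sweep_specs[0].population
                    if sim_cfg.sweep_specs
                    else panel.populations[-1]
                )
                _, _, truth = synth.simulate_expansion(sim_cfg)
                hap = synth.make_dh_panel(
                    truth.pop_freqs.loc[focal].to_numpy(),
                    truth.sites,
                    n_lines=p.get("n_lines", 400),
                    sweep_specs=[
                        s for s in sim_cfg.sweep_specs if s.population == focal
                    ],
                    seed=seed,
                )
            elif p.get("population"):
                hap = sweep_scan.dh_haplotypes(polarized, p["population"])
            if hap is not None:
                res = sweep_scan.ihs_scan(
                    hap,
                    maf_min=p.get("maf_min", sweep_scan.MAF_MIN),
                    ehh_cutoff=p.get("ehh_cutoff", sweep_scan.EHH_CUTOFF),
                    max_gap=p.get("max_gap", sweep_scan.MAX_GAP_BP),
                    n_bins=p.get("n_bins", sweep_scan.N_STD_BINS),
                )
                res = sweep_scan.empirical_classify(res)
                if "genes" in inputs:
                    genes = io_filters.read_genes_bed(inputs["genes"])
                    hits = res[res["significant"]]
                    if not hits.empty:
                        near = sweep_scan.nearest_gene(hits, genes)
                        res = res.merge(near, on=["chrom", "pos"], how="left")
                res.to_csv(out / "ihs.tsv", sep="\t", index=False)
                report["stages"]["ihs"] = {
                    "status": "ok",
                    "outputs": ["ihs.tsv"],
                    "n_significant": int(res["significant"].sum()),
                }

        # ---- rda ------------------------------------------------------
        if "rda" in stages and bioclim is not None and "fourfold" in inputs:
            p = params.get("rda", {})
            fourfold = io_filters.read_fourfold_sites(inputs["fourfold"])
            Y = env_rda.genotype_response(panel)
            pcs = env_rda.neutral_pcs(panel, fourfold, n_pcs=p.get("n_pcs", 2))
            bc = bioclim.set_index("population")
            pops_of_rows = [panel.pop_of_sample[s] for s in panel.sample_ids]
            clim_all = bc.loc[pops_of_rows, env_rda.BIOCLIM_VARS]
            latlon = bc.loc[pops_of_rows, ["latitude", "longitude"]].to_numpy(float)
            n_perm = p.get("n_perm", 199)
            sel = env_rda.forward_select(
                Y, clim_all.reset_index(drop=True),
                alpha=p.get("alpha", 0.05), n_perm=n_perm, seed=seed,
            )
            sel.to_csv(out / "rda_selected.tsv", sep="\t", index=False)
            clim = (
                clim_all[sel["variable"]].to_numpy(float)
                if not sel.empty
                else clim_all.to_numpy(float)
            )
            rep = env_rda.variance_partition(
                Y, clim, pcs, latlon, n_perm=n_perm, seed=seed
            )
            rep.models.to_csv(out / "rda_models.tsv", sep="\t", index=False)
            report["stages"]["rda"] = {
                "status": "ok",
                "outputs": ["rda_selected.tsv", "rda_models.tsv"],
                "selected": list(sel["variable"]),
                "best_model": rep.best_model,
            }

        # ---- load -----------------------------------------------------
        if "load" in stages and gerp is not None:
            p = params.get("load", {})
            kept, excluded, thr = load_calc.exclude_high_missing(
                polarized, quantile=p.get("missing_quantile", 0.95)
            )
            groups = {
                s: kept.pop_of_sample[s] for s in kept.sample_ids
            } if p.get("group_by_population", True) else None
            tab = load_calc.load_table(
                kept, gerp, group_of_sample=groups,
                high_del_threshold=p.get("high_del_threshold", 5.0),
            )
            tab.to_csv(out / "load.tsv", sep="\t", index=False)
            stage = {"status": "ok", "outputs": ["load.tsv"],
                     "n_excluded": len(excluded),
                     "missing_threshold": thr}
            if popmap is not None:
                corr = load_calc.load_correlates(
                    tab, popmap, [entry_south, entry_north], bioclim
                )
                corr.to_csv(out / "load_correlates.tsv", sep="\t", index=False)
                stage["outputs"].append("load_correlates.tsv")
            report["stages"]["load"] = stage
    except Exception as e:  # halt dependents, keep completed outputs
        report["stages"]["error"] = str(e)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, synth.SweepSpec):
        return obj.__dict__
    return obj
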