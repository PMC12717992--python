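"""Two-route range-expansion simulator with planted structure.

The generator emulates the demographic setting the analysis assumes: ~35
populations founded serially along two introduction routes from two entry
points (a south-western and a central-European one), each founding event a
binomial bottleneck followed by Wright-Fisher drift, with optional
symmetric neighbour migration. On top of the neutral frequencies it plants

* selective sweeps (for the EHH/iHS recovery experiments), realised as
  shared core haplotypes in DH panels,
* derived deleterious alleles carrying GERP scores, optionally accumulating
  along route edges (expansion-load surfing proxy),
* bioclimatic variables with linear lat/lon gradients plus noise.

Everything is frequency-level: statistics under test are site-wise, so no
recombination map is simulated except the sweep-window copying. All
randomness flows from one root seed through named substreams, and a
TruthTable records what was planted so recovery tests can check against it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_filters
from .panel import MISSING, GenotypePanel, HaplotypePanel

#: default entry coordinates: the Iberian and central-European introduction
#: points used throughout (lat, lon in decimal degrees).
ENTRY_SOUTH = (42.04, -8.64)
ENTRY_NORTH = (49.57, 3.328)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG derived from the root seed (order-independent)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class SweepSpec:
    population: str
    chrom: str
    pos: int
    final_freq: float
    core_window_bp: int = 15_000


@dataclass
class SimConfig:
    """Study conditions for the synthetic expansion.

    Defaults mirror the analysed system: 35 landrace-like populations on
    two routes, array-scale (thousands) of biallelic SNPs, partially
    inbred open-pollinated populations, and sparse missingness.
    """

    seed: int = 0
    n_pops: int = 35
    n_sites: int = 5000
    samples_per_pop: int = 24
    entry_points: tuple = (ENTRY_SOUTH, ENTRY_NORTH)
    founder_size: int = 40          # haploid founders per founding event
    deme_size: int = 200            # haploid deme size during drift
    generations_per_edge: int = 30
    migration_rate: float = 0.03    # per-generation neighbour exchange
    inter_cluster_factor: float = 0.1
    migration_generations: int | None = None  # default: generations_per_edge
    ancestral_freq_law: tuple = (0.8, 0.8)    # Beta(a, b)
    frac_deleterious: float = 0.10
    gerp_law: tuple = (2.0, 1.0)    # Gamma(shape, scale)
    gerp_high_frac: float = 0.03    # point mass above 5 within deleterious
    gerp_freq_coupling: float = 0.0  # >0 makes high-GERP derived alleles rarer
    sweep_specs: list = field(default_factory=list)
    env_gradient: dict | None = None
    inbreeding_f: float = 0.10
    missing_rate: float = 0.002
    mutation_accumulation: bool = True
    n_new_del_per_edge: int = 4
    new_mut_freq_law: tuple = (1.0, 4.0)      # Beta for surfing frequency
    branch_prob: float = 0.3
    site_spacing_bp: int = 300
    chrom: str = "1"
    frac_offclass_quality: float = 0.02

    def validate(self) -> None:
        if not 0 <= self.migration_rate <= 0.5:
            raise ValueError("migration_rate must be in [0, 0.5]")
        if self.n_pops < 2:
            raise ValueError("need at least the two entry populations")
        for s in self.sweep_specs:
            if not 0 <= s.final_freq <= 1:
                raise ValueError("sweep final_freq must be in [0, 1]")
        if not 0 <= self.frac_deleterious <= 1:
            raise ValueError("frac_deleterious in [0, 1]")


@dataclass
class TruthTable:
    pop_freqs: pd.DataFrame          # populations x sites derived freq
    sites: pd.DataFrame              # chrom, pos, ancestral-is-alt flag
    gerp: pd.DataFrame               # chrom, pos, gerp_score (deleterious only)
    sweep_specs: list
    env_coefficients: dict
    route_of_pop: dict
    depth_of_pop: dict
    cluster_of_pop: dict

    def to_json(self, path) -> None:
        payload = {
            "pop_freqs": {
                p: [round(float(v), 6) for v in row]
                for p, row in self.pop_freqs.iterrows()
            },
            "sites": self.sites.to_dict(orient="list"),
            "gerp": self.gerp.to_dict(orient="list"),
            "sweep_specs": [asdict(s) for s in self.sweep_specs],
            "env_coefficients": self.env_coefficients,
            "route_of_pop": self.route_of_pop,
            "depth_of_pop": self.depth_of_pop,
            "cluster_of_pop": self.cluster_of_pop,
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# route tree and coordinates
# ---------------------------------------------------------------------------

def build_route_tree(config: SimConfig) -> pd.DataFrame:
    """Spanning tree of populations over the two routes, with coordinates.

    Returns a DataFrame with population, parent (NaN for the two entries),
    route ("south"/"north"), cluster ("Western"/"Eastern"), depth,
    latitude, longitude. The southern route heads north-east from Iberia,
    the northern route east across central Europe; children step away from
    their parent with jitter, so coordinates track route depth.
    """
    rng = substream(config.seed, "route_tree")
    pops = [f"P{i:02d}" for i in range(config.n_pops)]
    rows = [
        {"population": pops[0], "parent": None, "route": "south",
         "cluster": "Western", "depth": 0,
         "latitude": config.entry_points[0][0],
         "longitude": config.entry_points[0][1]},
        {"population": pops[1], "parent": None, "route": "north",
         "cluster": "Eastern", "depth": 0,
         "latitude": config.entry_points[1][0],
         "longitude": config.entry_points[1][1]},
    ]
    tip = {"south": rows[0], "north": rows[1]}
    members = {"south": [rows[0]], "north": [rows[1]]}
    steps = {"south": (0.40, 1.10), "north": (0.06, 1.40)}
    for i in range(2, config.n_pops):
        route = "south" if i % 2 == 0 else "north"
        if rng.random() < config.branch_prob and len(members[route]) > 1:
            parent = members[route][int(rng.integers(len(members[route]) - 1))]
        else:
            parent = tip[route]
        dlat, dlon = steps[route]
        row = {
            "population": pops[i],
            "parent": parent["population"],
            "route": route,
            "cluster": "Western" if route == "south" else "Eastern",
            "depth": parent["depth"] + 1,
            "latitude": float(
                np.clip(parent["latitude"] + dlat + rng.normal(0, 0.25), -90, 90)
            ),
            "longitude": float(
                np.clip(parent["longitude"] + dlon + rng.normal(0, 0.25), -180, 180)
            ),
        }
        rows.append(row)
        members[route].append(row)
        if row["depth"] >= tip[route]["depth"]:
            tip[route] = row
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frequency simulation
# ---------------------------------------------------------------------------

def _drift(rng, p: np.ndarray, size: int, generations: int) -> np.ndarray:
    for _ in range(generations):
        p = rng.binomial(size, p) / size
    return p


def simulate_expansion(
    config: SimConfig,
) -> tuple[GenotypePanel, pd.DataFrame, TruthTable]:
    """Run the serial-founder expansion and sample genotypes.

    Ancestral frequencies are drawn once from Beta(a, b); each route edge
    applies a binomial founder bottleneck then ``generations_per_edge``
    Wright-Fisher updates at ``deme_size``; optional symmetric neighbour
    migration mixes frequencies afterwards. Genotypes are drawn per
    population under inbreeding-adjusted Hardy-Weinberg,
    P(het) = 2pq(1-F). Returns (panel in VCF alt coding with INFO/AA-style
    ancestral annotation, population map, truth table).
    """
    config.validate()
    tree = build_route_tree(config)
    rng_anc = substream(config.seed, "ancestral")
    a, b = config.ancestral_freq_law
    p0 = rng_anc.beta(a, b, size=config.n_sites)

    # Deleterious sites carry GERP scores; a reserved slice of them starts
    # ancestral-fixed and is activated edge-by-edge when mutation
    # accumulation is on.
    rng_gerp = substream(config.seed, "gerp")
    n_del = int(round(config.frac_deleterious * config.n_sites))
    del_idx = rng_gerp.choice(config.n_sites, size=n_del, replace=False)
    shape, scale = config.gerp_law
    gerp_scores = rng_gerp.gamma(shape, scale, size=n_del)
    high = rng_gerp.random(n_del) < config.gerp_high_frac
    gerp_scores[high] = 5.0 + rng_gerp.exponential(1.0, size=int(high.sum()))
    if config.gerp_freq_coupling > 0:
        # negative-selection proxy: push ancestral freq of high-GERP sites down
        p0[del_idx] *= np.exp(-config.gerp_freq_coupling * gerp_scores)

    n_edges = config.n_pops - 2 + 2  # every population is founded once
    mut_pool: list[np.ndarray] = []
    if config.mutation_accumulation and config.n_new_del_per_edge > 0:
        need = config.n_new_del_per_edge * n_edges
        pool = del_idx[: min(need, n_del)]
        p0[pool] = 0.0
        mut_pool = list(pool)

    rng_drift = substream(config.seed, "drift")
    freqs: dict[str, np.ndarray] = {}
    pool_cursor = 0
    fa, fb = config.new_mut_freq_law
    for _, row in tree.iterrows():
        parent = row["parent"]
        p = p0.copy() if parent is None else freqs[parent].copy()
        p = rng_drift.binomial(config.founder_size, p) / config.founder_size
        if config.mutation_accumulation:
            take = mut_pool[pool_cursor : pool_cursor + config.n_new_del_per_edge]
            pool_cursor += len(take)
            if take:
                p[np.asarray(take)] = rng_drift.beta(fa, fb, size=len(take))
        p = _drift(rng_drift, p, config.deme_size, config.generations_per_edge)
        freqs[row["population"]] = p

    # neighbour migration over the tree edges (+ a weak inter-cluster link)
    m = config.migration_rate
    n_mig = (
        config.migration_generations
        if config.migration_generations is not None
        else config.generations_per_edge
    )
    if m > 0 and n_mig > 0:
        edges = [
            (r["population"], r["parent"], 1.0)
            for _, r in tree.iterrows()
            if r["parent"] is not None
        ]
        edges.append(
            (tree["population"].iloc[0], tree["population"].iloc[1],
             config.inter_cluster_factor)
        )
        neighbours: dict[str, list[tuple[str, float]]] = {
            p: [] for p in tree["population"]
        }
        for u, v, w in edges:
            neighbours[u].append((v, w))
            neighbours[v].append((u, w))
        for _ in range(n_mig):
            new = {}
            for pop, nbrs in neighbours.items():
                wsum = sum(w for _, w in nbrs)
                mix = sum(w * freqs[q] for q, w in nbrs) / wsum
                new[pop] = (1 - m) * freqs[pop] + m * mix
            for pop in new:
                freqs[pop] = _drift(rng_drift, new[pop], config.deme_size, 1)

    # planted sweeps: pin the focal derived frequency in the focal population
    positions = (
        1 + config.site_spacing_bp * np.arange(config.n_sites)
    ).astype(np.int64)
    pos_index = {int(pp): i for i, pp in enumerate(positions)}
    for sw in config.sweep_specs:
        if sw.chrom != config.chrom or int(sw.pos) not in pos_index:
            raise ValueError(f"sweep position {sw.chrom}:{sw.pos} not simulated")
        freqs[sw.population][pos_index[int(sw.pos)]] = sw.final_freq

    # site annotation: ref/alt bases, ancestral label, quality class
    rng_sites = substream(config.seed, "sites")
    bases = np.array(list("ACGT"))
    anc_base = bases[rng_sites.integers(4, size=config.n_sites)]
    der_base = np.array(
        [rng_sites.choice([x for x in "ACGT" if x != ab]) for ab in anc_base]
    )
    anc_is_alt = rng_sites.random(config.n_sites) < 0.5
    ref = np.where(anc_is_alt, der_base, anc_base)
    alt = np.where(anc_is_alt, anc_base, der_base)
    qc = np.where(
        rng_sites.random(config.n_sites) < config.frac_offclass_quality,
        "Other",
        rng_sites.choice(
            ["PolyHighResolution", "MonoHighResolution", "NoMinorHom"],
            size=config.n_sites,
            p=[0.9, 0.05, 0.05],
        ),
    )
    sites = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "ancestral": anc_base,
            "quality_class": qc,
        }
    )

    # genotype sampling under inbreeding-adjusted HWE, then alt coding
    rng_geno = substream(config.seed, "genotypes")
    F = config.inbreeding_f
    sample_ids, pop_of_sample, blocks = [], {}, []
    for _, row in tree.iterrows():
        pop = row["population"]
        p = freqs[pop]
        p_hom_der = p**2 + F * p * (1 - p)
        p_het = 2 * p * (1 - p) * (1 - F)
        u = rng_geno.random((config.samples_per_pop, config.n_sites))
        derived = np.where(
            u < p_hom_der, 2, np.where(u < p_hom_der + p_het, 1, 0)
        ).astype(np.int8)
        if config.missing_rate > 0:
            miss = rng_geno.random(derived.shape) < config.missing_rate
            derived[miss] = MISSING
        blocks.append(derived)
        for k in range(config.samples_per_pop):
            sid = f"{pop}_s{k:03d}"
            sample_ids.append(sid)
            pop_of_sample[sid] = pop
    derived_dosage = np.vstack(blocks)
    dosage = derived_dosage.copy()
    flip_cols = np.flatnonzero(anc_is_alt)
    blk = dosage[:, flip_cols]
    called = blk != MISSING
    blk[called] = 2 - blk[called]
    dosage[:, flip_cols] = blk

    panel = GenotypePanel(
        sample_ids=sample_ids,
        pop_of_sample=pop_of_sample,
        sites=sites,
        dosage=dosage,
        coding="alt",
    )
    popmap = tree[["population", "latitude", "longitude", "cluster"]].copy()
    gerp = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions[np.sort(del_idx)],
            "gerp_score": gerp_scores[np.argsort(del_idx)],
        }
    )
    truth = TruthTable(
        pop_freqs=pd.DataFrame(
            np.vstack([freqs[p] for p in tree["population"]]),
            index=list(tree["population"]),
        ),
        sites=pd.DataFrame(
            {"chrom": config.chrom, "pos": positions, "anc_is_alt": anc_is_alt}
        ),
        gerp=gerp,
        sweep_specs=list(config.sweep_specs),
        env_coefficients={},
        route_of_pop=dict(zip(tree["population"], tree["route"])),
        depth_of_pop={p: int(d) for p, d in zip(tree["population"], tree["depth"])},
        cluster_of_pop=dict(zip(tree["population"], tree["cluster"])),
    )
    return panel, popmap, truth


# ---------------------------------------------------------------------------
# DH panels with planted sweeps
# ---------------------------------------------------------------------------

def make_dh_panel(
    pop_freqs: np.ndarray,
    sites: pd.DataFrame,
    n_lines: int,
    sweep_specs: list[SweepSpec] | None = None,
    seed: int = 0,
) -> HaplotypePanel:
    """Draw DH haplotypes from population frequencies with sweep cores.

    Haplotypes are drawn site-wise independently (no background LD); then,
    for each sweep, carriers of the focal derived allele are overwritten
    with one shared template haplotype across the core window with
    probability equal to the sweep's final frequency (its completeness),
    producing the elevated haplotype homozygosity a real sweep leaves.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 DH lines")
    rng = np.random.default_rng(seed)
    p = np.asarray(pop_freqs, float)
    H = (rng.random((n_lines, p.size)) < p).astype(np.uint8)
    pos = sites["pos"].to_numpy()
    for sw in sweep_specs or []:
        on = (sites["chrom"] == sw.chrom).to_numpy()
        hit = on & (pos == sw.pos)
        if not hit.any():
            raise ValueError(f"sweep position {sw.chrom}:{sw.pos} not in sites")
        focal = int(np.flatnonzero(hit)[0])
        window = on & (np.abs(pos - sw.pos) <= sw.core_window_bp // 2)
        template = (rng.random(int(window.sum())) < p[window]).astype(np.uint8)
        template[np.flatnonzero(window) == focal] = 1
        H[:, focal] = rng.random(n_lines) < sw.final_freq
        carriers = np.flatnonzero(H[:, focal] == 1)
        copy = carriers[rng.random(carriers.size) < sw.final_freq]
        H[np.ix_(copy, np.flatnonzero(window))] = template
        H[copy, focal] = 1
    return HaplotypePanel(
        line_ids=[f"dh{i:04d}" for i in range(n_lines)],
        sites=sites[["chrom", "pos"]].copy(),
        H=H,
    )


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def default_env_gradient() -> dict:
    """Per-variable (intercept, lat slope, lon slope, noise sd).

    Three variables carry strong planted gradients — a driest-quarter
    temperature falling with latitude, a precipitation seasonality rising
    eastward, and a coldest-quarter precipitation falling eastward — the
    rest are weakly structured noise, loosely on WorldClim-like scales.
    """
    grad = {}
    for i in range(1, 20):
        grad[f"bio{i}"] = (10.0 + i, 0.08, 0.04, 1.0)
    grad["bio9"] = (60.0, -1.3, 0.15, 0.9)    # mean temp of driest quarter
    grad["bio15"] = (20.0, 0.25, 0.90, 1.2)   # precipitation seasonality
    grad["bio19"] = (400.0, 0.5, -6.0, 8.0)   # precipitation of coldest quarter
    return grad


def attach_bioclim(
    popmap: pd.DataFrame,
    env_gradient: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Bioclim table: each variable = intercept + a·lat + b·lon + noise.

    Returns (table with population, bio1..bio19, latitude, longitude;
    the coefficient dict actually used — the truth for recovery tests).
    """
    need = {"population", "latitude", "longitude"}
    if not need <= set(popmap.columns):
        raise ValueError("popmap needs population, latitude, longitude")
    grad = env_gradient if env_gradient is not None else default_env_gradient()
    rng = substream(seed, "bioclim")
    out = popmap[["population", "latitude", "longitude"]].copy()
    lat = out["latitude"].to_numpy(float)
    lon = out["longitude"].to_numpy(float)
    for var in [f"bio{i}" for i in range(1, 20)]:
        c, a, b, sd = grad[var]
        noise = rng.normal(0, sd, size=len(out)) if sd > 0 else 0.0
        out[var] = c + a * lat + b * lon + noise
    cols = ["population"] + [f"bio{i}" for i in range(1, 20)] + [
        "latitude", "longitude"
    ]
    return out[cols], grad


# ---------------------------------------------------------------------------
# bundle writer (the exact formats io_filters reads)
# ---------------------------------------------------------------------------

def make_genes(config: SimConfig, n_genes: int = 40) -> pd.DataFrame:
    """Random gene intervals spanning the simulated chromosome (1-based)."""
    rng = substream(config.seed, "genes")
    span = config.n_sites * config.site_spacing_bp
    starts = np.sort(rng.integers(1, max(2, span - 2000), size=n_genes))
    lengths = rng.integers(500, 3000, size=n_genes)
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": np.minimum(starts + lengths, span),
            "gene_id": [f"gene{i:03d}" for i in range(n_genes)],
        }
    )


def write_bundle(config: SimConfig, out_dir) -> dict:
    """Simulate and emit VCF + TSV/BED companions + truth JSON.

    Returns the paths written. Output is deterministic in the config
    (byte-identical across reruns with the same config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, popmap, truth = simulate_expansion(config)
    bioclim, coeffs = attach_bioclim(popmap, config.env_gradient, config.seed)
    truth.env_coefficients = {k: list(v) for k, v in coeffs.items()}
    genes = make_genes(config)

    paths = {
        "vcf": out / "genotypes.vcf",
        "popmap": out / "popmap.tsv",
        "coords": out / "coordinates.tsv",
        "gerp": out / "gerp.tsv",
        "bioclim": out / "bioclim.tsv",
        "genes": out / "genes.bed",
        "fourfold": out / "fourfold_sites.tsv",
        "truth": out / "truth.json",
    }
    io_filters.write_vcf(panel, paths["vcf"])
    pd.DataFrame(
        {"sample": panel.sample_ids,
         "population": [panel.pop_of_sample[s] for s in panel.sample_ids]}
    ).to_csv(paths["popmap"], sep="\t", index=False)
    popmap.to_csv(paths["coords"], sep="\t", index=False)
    truth.gerp.to_csv(paths["gerp"], sep="\t", index=False)
    bioclim.to_csv(paths["bioclim"], sep="\t", index=False)
    bed = genes.copy()
    bed["start"] = bed["start"] - 1  # back to 0-based half-open
    bed.to_csv(paths["genes"], sep="\t", index=False, header=False)
    # truth-neutral sites (no GERP score) stand in for 4-fold degenerate sites
    scored = set(zip(truth.gerp["chrom"], truth.gerp["pos"]))
    neutral = truth.sites[
        ~truth.sites.apply(lambda r: (r["chrom"], r["pos"]) in scored, axis=1)
    ]
    neutral[["chrom", "pos"]].to_csv(paths["fourfold"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
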