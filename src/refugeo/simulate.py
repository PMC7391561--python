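"""Synthetic data generators for every analysis stage.

Three generators produce inputs with the statistical structure the
pipeline assumes, so the whole chain is testable without any download:

* :func:`simulate_serial_founder` — a stepping-stone serial founder
  model: demes on a lon/lat grid are colonized wavefront-style from one
  edge; each new deme is founded by K individuals drawn without
  replacement from its parent, regrows to deme size N, and then drifts
  for a few Wright-Fisher generations.
  Diversity and rarity therefore decline away from the source, the
  gradient the refugium inference exploits.
* :func:`simulate_occurrence` — cytotype occurrence over populations:
  correlated Gaussian ecological covariates, Bernoulli apomict
  presences, and a Bernoulli sexual presence with logistic probability
  ``logit = b0 + b_eco.x + b_hist.cd + b_apo.z``.
* :func:`make_synthetic_dem` — flat, valley-corridor, or ridge relief
  rasters for the cost-distance stage.

All randomness flows from a single seed through named substreams so the
generators are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from refugeo.datatypes import AFLPMatrix, HaplotypeData, Raster
from refugeo.costdist import CostSurface, accumulate_cost

STUDY_BOUNDS = (9.4, 44.7, 13.9, 48.1)  # lon_min, lat_min, lon_max, lat_max

_SUBSTREAMS = ("landscape", "colonization", "drift", "sampling", "occurrence")


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, _SUBSTREAMS.index(name)])


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

def make_synthetic_dem(
    bounds: tuple[float, float, float, float] = STUDY_BOUNDS,
    cell_size: float = 0.1,
    relief: str = "flat",
    seed: int = 0,
) -> Raster:
    """Deterministic synthetic elevation raster (metres).

    ``flat``: uniform 500 m.  ``valley``: high plateau with a cheap
    north-south corridor at the central longitude.  ``ridge``: lowland
    with an expensive east-west ridge across the middle.
    """
    lon_min, lat_min, lon_max, lat_max = bounds
    n_cols = int(round((lon_max - lon_min) / cell_size))
    n_rows = int(round((lat_max - lat_min) / cell_size))
    rng = _substream(seed, "landscape")
    if relief == "flat":
        values = np.full((n_rows, n_cols), 500.0)
    elif relief == "valley":
        values = np.full((n_rows, n_cols), 2500.0)
        half_width = max(n_cols // 8, 1)
        mid = n_cols // 2
        values[:, mid - half_width : mid + half_width + 1] = 300.0
        values += rng.uniform(0.0, 10.0, size=values.shape)
    elif relief == "ridge":
        values = np.full((n_rows, n_cols), 300.0)
        half_width = max(n_rows // 10, 1)
        mid = n_rows // 2
        values[mid - half_width : mid + half_width + 1, :] = 3000.0
        values += rng.uniform(0.0, 10.0, size=values.shape)
    else:
        raise ValueError(f"unknown relief {relief!r}")
    return Raster(values=values, xll=lon_min, yll=lat_min, cellsize=cell_size)


def edge_source_mask(template: Raster, edge: str) -> Raster:
    """Binary raster marking one full edge row (north or south) as source."""
    mask = np.zeros_like(template.values)
    if edge == "south":
        mask[-1, :] = 1.0  # row 0 is north in raster convention
    elif edge == "north":
        mask[0, :] = 1.0
    else:
        raise ValueError("source_edge must be 'north' or 'south'")
    return template.copy_with(mask)


# ---------------------------------------------------------------------------
# serial founder colonization
# ---------------------------------------------------------------------------

@dataclass
class FounderSimConfig:
    """Parameters of the stepping-stone serial founder simulation.

    Defaults emulate the scale of a real Alpine transect dataset: 68
    genotyped populations of 4 individuals, 370 dominant loci, and a
    short plastid alignment; the drift parameters (founder size K,
    deme size N, generations per colonization step) are set to produce a
    clear diversity decline from the source edge.
    """

    bounds: tuple[float, float, float, float] = STUDY_BOUNDS
    cell_size: float = 0.1
    source_edge: str = "south"
    n_pops: int = 68
    individuals_per_pop: int = 4
    n_loci: int = 370
    n_haplotypes_source: int = 8
    founder_size: int = 8  # K founding individuals per new deme
    deme_size: int = 50  # Wright-Fisher N after founding
    generations_per_step: int = 5
    relief: str = "flat"
    dominant: bool = True  # band presence = 1 - (1-q)^2; else haploid bands
    seq_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founder_size > self.deme_size:
            raise ValueError("founder_size K must be <= deme_size N")
        for name in ("n_pops", "individuals_per_pop", "n_loci", "n_haplotypes_source",
                     "founder_size", "deme_size", "seq_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _haplotype_sequences(n_hap: int, length: int, rng: np.random.Generator) -> list[str]:
    """Build n_hap aligned sequences: an ancestral sequence, two private
    substitutions per derived haplotype, plus one 3-bp deletion in the
    last haplotype so indel coding is exercised."""
    bases = np.array(list("ACGT"))
    anc = rng.choice(bases, size=length)
    seqs = [anc.copy()]
    sites = rng.choice(length, size=2 * (n_hap - 1), replace=False)
    for h in range(1, n_hap):
        s = anc.copy()
        for pos in sites[2 * (h - 1) : 2 * h]:
            s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
        seqs.append(s)
    out = ["".join(s) for s in seqs]
    if n_hap >= 2:
        gap_start = length // 2
        last = list(out[-1])
        last[gap_start : gap_start + 3] = "---"
        out[-1] = "".join(last)
    return out


def _colonization_order(cost_surface: CostSurface) -> tuple[np.ndarray, np.ndarray]:
    """Deme order and parent assignment from the accumulated-cost surface.

    Demes are colonized in order of increasing accumulated cost (wavefront
    breadth-first); each non-source deme is founded from its 8-neighbor
    with the smallest accumulated cost, ties broken by (row, col).
    """
    acc = cost_surface.raster.values
    nrows, ncols = acc.shape
    flat = acc.ravel()
    if not np.isfinite(flat).all() or (flat == cost_surface.raster.nodata).any():
        raise ValueError("unreachable demes in the colonization landscape")
    order = np.lexsort((np.arange(flat.size) % ncols, np.arange(flat.size) // ncols, flat))
    parent = np.full(flat.size, -1, dtype=int)
    for k in order:
        r, c = divmod(k, ncols)
        if cost_surface.source_mask[r, c]:
            continue
        best = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    cand = (flat[rr * ncols + cc], rr, cc)
                    if best is None or cand < best:
                        best = cand
        parent[k] = best[1] * ncols + best[2]
    return order, parent


def simulate_serial_founder(
    config: FounderSimConfig,
) -> tuple[pd.DataFrame, AFLPMatrix, HaplotypeData, str]:
    """Run the serial founder colonization and sample populations.

    Returns ``(population_table, aflp, haplotypes, true_source)`` in the
    exact shapes the analysis pipeline consumes.
    """
    cfg = config
    dem = make_synthetic_dem(cfg.bounds, cfg.cell_size, cfg.relief, cfg.seed)
    sources = edge_source_mask(dem, cfg.source_edge)
    surface = accumulate_cost(dem, sources)
    order, parent = _colonization_order(surface)

    rng_drift = _substream(cfg.seed, "drift")
    rng_col = _substream(cfg.seed, "colonization")
    rng_samp = _substream(cfg.seed, "sampling")

    n_demes = dem.n_rows * dem.n_cols
    two_k = 2 * cfg.founder_size
    two_n = 2 * cfg.deme_size
    # deme state as integer allele-copy counts, so founding with K = N and
    # no drift generations copies the parent deme exactly
    c = np.empty((n_demes, cfg.n_loci), dtype=np.int64)
    h = np.empty((n_demes, cfg.n_haplotypes_source), dtype=np.int64)
    c_source = np.round(rng_col.uniform(0.1, 0.9, size=cfg.n_loci) * two_n).astype(np.int64)
    h_source = np.full(cfg.n_haplotypes_source, cfg.deme_size // cfg.n_haplotypes_source)
    h_source[: cfg.deme_size % cfg.n_haplotypes_source] += 1

    for k in order:
        if parent[k] < 0:  # source deme: the refugial pool itself, no drift
            c[k] = c_source
            h[k] = h_source
            continue
        # founding bottleneck: K individuals drawn without replacement
        ck = rng_drift.hypergeometric(c[parent[k]], two_n - c[parent[k]], two_k)
        hk = rng_drift.multivariate_hypergeometric(h[parent[k]], cfg.founder_size)
        if cfg.founder_size < cfg.deme_size:  # regrow to deme size N
            ck = rng_drift.binomial(two_n, ck / two_k)
            hk = rng_drift.multinomial(cfg.deme_size, hk / cfg.founder_size)
        for _ in range(cfg.generations_per_step):
            ck = rng_drift.binomial(two_n, ck / two_n)
            hk = rng_drift.multinomial(cfg.deme_size, hk / cfg.deme_size)
        c[k] = ck
        h[k] = hk

    q = c / two_n
    hap = h / cfg.deme_size

    # sample populations
    pop_demes = rng_samp.choice(n_demes, size=cfg.n_pops, replace=False)
    ncols = dem.n_cols
    hap_seqs = _haplotype_sequences(cfg.n_haplotypes_source, cfg.seq_length, rng_samp)

    pop_ids, lons, lats = [], [], []
    individuals: list[str] = []
    pop_of: dict[str, str] = {}
    band_rows = []
    ind_seqs: list[str] = []
    for i, deme in enumerate(pop_demes):
        pop = f"P{i + 1:03d}"
        r, c = divmod(int(deme), ncols)
        lon, lat = dem.cell_center(r, c)
        jitter = rng_samp.uniform(-0.3, 0.3, size=2) * cfg.cell_size
        pop_ids.append(pop)
        lons.append(lon + jitter[0])
        lats.append(lat + jitter[1])
        for j in range(cfg.individuals_per_pop):
            ind = f"{pop}_i{j + 1}"
            individuals.append(ind)
            pop_of[ind] = pop
            if cfg.dominant:
                p_band = 1.0 - (1.0 - q[deme]) ** 2
            else:
                p_band = q[deme]
            band_rows.append(rng_samp.binomial(1, p_band))
            h_idx = rng_samp.choice(cfg.n_haplotypes_source, p=hap[deme] / hap[deme].sum())
            ind_seqs.append(hap_seqs[h_idx])

    table = pd.DataFrame(
        {
            "pop_id": pop_ids,
            "lon": lons,
            "lat": lats,
            "present_4x": 1,
            "present_5x": 0,
            "present_7x": 0,
            "present_8x": 0,
            "elevation": 500.0,
            "inclination": 15.0,
            "aspect": 90.0,
            "land_use": 0,
            "ndvi": 0.5,
            "bio04": 6000.0,
            "bio12": 1000.0,
            "bio15": 30.0,
        }
    )
    aflp = AFLPMatrix(
        individuals=individuals, pop_of=pop_of, bands=np.asarray(band_rows, dtype=int)
    )
    haplotypes = HaplotypeData(
        individuals=list(individuals), pop_of=dict(pop_of), alignment=ind_seqs
    )
    return table, aflp, haplotypes, cfg.source_edge


# ---------------------------------------------------------------------------
# cytotype occurrence
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSimConfig:
    """Parameters of the logistic cytotype-occurrence generator.

    Coefficients are on the prepared (z-scored) predictor scale.  The
    default effect sizes mirror the magnitudes reported for an Alpine
    sexual-apomictic transect: strong negative apomict-presence effects,
    moderate ecological effects, and no colonization-history effect.
    """

    n_pops: int = 235
    beta0: float = 3.75
    beta_eco: tuple[float, ...] = (-0.33, 0.58, 0.12, -2.24, 0.06, 0.0, -0.71, 0.22)
    beta_hist: float = 0.0
    beta_apo: tuple[float, ...] = (-3.65, -1.56, -2.49)
    apo_prevalence: tuple[float, ...] = (0.45, 0.25, 0.12)
    eco_correlation: float = 0.0  # exchangeable corr. of continuous covariates
    land_use_prevalence: float = 0.5
    bounds: tuple[float, float, float, float] = STUDY_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta_eco) != 8:
            raise ValueError("beta_eco must have 8 entries")
        if len(self.beta_apo) != len(self.apo_prevalence) != 3:
            raise ValueError("beta_apo and apo_prevalence must have 3 entries")
        if not all(0.0 < p < 1.0 for p in self.apo_prevalence):
            raise ValueError("apomict prevalences must be in (0, 1)")
        n_cont = 7
        corr = np.full((n_cont, n_cont), self.eco_correlation)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("covariate correlation structure is not positive definite")
        self._corr = corr


def simulate_occurrence(config: OccurrenceSimConfig) -> pd.DataFrame:
    """Simulate a cytotype-occurrence population table.

    Continuous covariates are drawn from a correlated Gaussian and mapped
    to realistic raw units (the pipeline z-scores them back); apomict
    presences are independent Bernoulli; sexual presence is Bernoulli
    with ``logit = b0 + b_eco.x + b_hist.cd + b_apo.z`` evaluated on the
    standardized scale.
    """
    cfg = config
    rng = _substream(cfg.seed, "occurrence")
    n = cfg.n_pops
    z = rng.multivariate_normal(np.zeros(7), cfg._corr, size=n, method="cholesky")
    land_use = rng.binomial(1, cfg.land_use_prevalence, size=n)
    cd_z = rng.standard_normal(n)
    apo = np.column_stack(
        [rng.binomial(1, p, size=n) for p in cfg.apo_prevalence]
    )
    # predictor order: elevation, inclination, aspect, land_use, ndvi, bio04, bio12, bio15
    x = np.column_stack([z[:, 0], z[:, 1], z[:, 2], land_use, z[:, 3], z[:, 4], z[:, 5], z[:, 6]])
    logit = (
        cfg.beta0
        + x @ np.asarray(cfg.beta_eco)
        + cfg.beta_hist * cd_z
        + apo @ np.asarray(cfg.beta_apo)
    )
    sexual = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit)))
    lon_min, lat_min, lon_max, lat_max = cfg.bounds
    table = pd.DataFrame(
        {
            "pop_id": [f"P{i + 1:03d}" for i in range(n)],
            "lon": rng.uniform(lon_min, lon_max, size=n),
            "lat": rng.uniform(lat_min, lat_max, size=n),
            "present_4x": sexual,
            "present_5x": apo[:, 0],
            "present_7x": apo[:, 1],
            "present_8x": apo[:, 2],
            "elevation": 800.0 + 400.0 * z[:, 0],
            "inclination": np.clip(20.0 + 10.0 * z[:, 1], 0.0, None),
            "aspect": np.clip(90.0 + 40.0 * z[:, 2], 0.0, 180.0),
            "land_use": land_use,
            "ndvi": 0.5 + 0.15 * z[:, 3],
            "bio04": 6000.0 + 800.0 * z[:, 4],
            "bio12": (10.0 + 1.5 * z[:, 5]) ** 3,
            "bio15": 30.0 + 8.0 * z[:, 6],
            "cost_distance": 500.0 + 200.0 * cd_z,
        }
    )
    return table
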