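"""Population-genetic indices, Jost's D_est and the Mantel test.

Four per-population indices summarize genetic variation:

* haplotype diversity ``h = n/(n-1) * (1 - sum x_i^2)`` with ``x_i`` the
  haplotype relative frequencies — the unbiased probability that two
  sequences drawn without replacement differ;
* nucleotide diversity ``pi`` — the mean pairwise per-site difference,
  with coded indel characters appended to the alignment as extra binary
  sites;
* gene diversity for dominant markers — per-locus
  ``H_l = n/(n-1) * 2 p_l (1 - p_l)`` (``p_l`` the band frequency),
  averaged over loci;
* rarity (frequency-down-weighted marker values, DW) — per individual,
  the sum over loci of the population's share of each band's
  dataset-wide occurrences.  High values flag accumulations of rare
  bands typical of long-isolated, refugial populations.

Differentiation uses Jost's D_est on band frequencies; isolation by
distance is tested with a one-sided permutation Mantel test.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd

from refugeo.datatypes import AFLPMatrix, DistanceMatrix, HaplotypeData
from refugeo.errors import UndefinedIndexError

log = logging.getLogger("refugeo")

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# cpDNA indices
# ---------------------------------------------------------------------------

def haplotype_diversity(counts) -> float:
    """Unbiased haplotype diversity from haplotype counts of one population."""
    counts = np.asarray(counts, dtype=float)
    if (counts <= 0).any():
        raise ValueError("haplotype counts must be positive")
    n = counts.sum()
    if n < 2:
        raise UndefinedIndexError("haplotype diversity needs n >= 2")
    freqs = counts / n
    return float(n / (n - 1.0) * (1.0 - (freqs**2).sum()))


def _seq_diff(a: str, b: str) -> int:
    """Number of differing nucleotide sites; sites with a gap or N in
    either sequence are not compared (indels are scored separately)."""
    ok = {"A", "C", "G", "T"}
    return sum(1 for x, y in zip(a, b) if x in ok and y in ok and x != y)


def nucleotide_diversity(seqs: list[str], indel_chars: np.ndarray | None = None) -> float:
    """Mean pairwise per-site difference within one population.

    Coded indel characters (one binary column per gap event) count as
    additional sites appended to the alignment length.
    """
    n = len(seqs)
    if n < 2:
        raise UndefinedIndexError("nucleotide diversity needs n >= 2")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    if indel_chars is None:
        indel_chars = np.zeros((n, 0), dtype=int)
    indel_chars = np.asarray(indel_chars)
    length = len(seqs[0]) + indel_chars.shape[1]
    total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        d = _seq_diff(seqs[i], seqs[j])
        if indel_chars.shape[1]:
            d += int((indel_chars[i] != indel_chars[j]).sum())
        total += d / length
    return total / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# AFLP indices
# ---------------------------------------------------------------------------

def aflp_gene_diversity(bands: np.ndarray) -> float:
    """Dominant-marker gene diversity of one population.

    Band (phenotype) frequencies are used directly, matching the AFLPdat
    convention; no dominant-marker null-allele correction is applied.
    """
    bands = np.asarray(bands, dtype=float)
    n, n_loci = bands.shape
    if n < 2:
        raise UndefinedIndexError("gene diversity needs n >= 2")
    if n_loci < 1:
        raise ValueError("at least one locus required")
    p = bands.mean(axis=0)
    h = n / (n - 1.0) * 2.0 * p * (1.0 - p)
    return float(h.mean())


def aflp_rarity(matrix: AFLPMatrix) -> pd.Series:
    """Frequency-down-weighted marker values (DW) per population.

    ``DW_j = (1/n_j) * sum_l occ_{jl} / occ_l`` where ``occ_{jl}`` is the
    band count of locus ``l`` in population ``j`` and ``occ_l`` its count
    in the whole dataset.  Loci absent from the entire dataset carry no
    information and are dropped with a warning.  The values satisfy the
    conservation identity ``sum_j n_j * DW_j = n_retained_loci``.
    """
    if matrix.n_individuals == 0 or matrix.n_loci == 0:
        raise ValueError("empty AFLP matrix")
    totals = matrix.bands.sum(axis=0).astype(float)
    keep = totals > 0
    if not keep.all():
        log.warning("dropping %d all-zero AFLP loci", int((~keep).sum()))
    if not keep.any():
        raise ValueError("no locus occurs in the dataset")
    out = {}
    for pop, rows in matrix.populations().items():
        occ = rows[:, keep].sum(axis=0).astype(float)
        out[pop] = float((occ / totals[keep]).sum() / rows.shape[0])
    return pd.Series(out, name="rarity")


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _dest_from_freqs(p: np.ndarray) -> float:
    """Jost's D_est from a (k populations x L loci) band-frequency array.

    Per-locus within-population diversity ``H_S = mean_j 2 p_j (1-p_j)``
    and total diversity ``H_T = 2 p_bar (1-p_bar)`` are averaged over
    loci, then combined as
    ``D = (H_T - H_S) / (1 - H_S) * k/(k-1)``.
    """
    k = p.shape[0]
    hs = (2.0 * p * (1.0 - p)).mean(axis=0)
    pbar = p.mean(axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs_bar = hs.mean()
    ht_bar = ht.mean()
    if hs_bar >= 1.0:
        return np.nan
    return float((ht_bar - hs_bar) / (1.0 - hs_bar) * k / (k - 1.0))


def jost_dest(matrix: AFLPMatrix, min_n: int = 2) -> float:
    """Global Jost's D_est across all populations of an AFLP matrix."""
    pops = matrix.populations()
    freqs = []
    for pop, rows in sorted(pops.items()):
        if rows.shape[0] < min_n:
            raise ValueError(f"population {pop!r} has n < {min_n}")
        freqs.append(rows.mean(axis=0))
    if len(freqs) < 2:
        raise ValueError("D_est needs at least 2 populations")
    return _dest_from_freqs(np.asarray(freqs))


def pairwise_dest(matrix: AFLPMatrix, min_n: int = 2) -> DistanceMatrix:
    """Pairwise Jost's D_est (k = 2) between all population pairs.

    Populations with fewer than ``min_n`` individuals are excluded with a
    warning.
    """
    pops = matrix.populations()
    labels = []
    freqs = []
    for pop, rows in pops.items():
        if rows.shape[0] < min_n:
            log.warning("excluding population %r (n < %d) from pairwise D_est", pop, min_n)
            continue
        labels.append(pop)
        freqs.append(rows.mean(axis=0))
    n = len(labels)
    if n < 2:
        raise ValueError("pairwise D_est needs at least 2 usable populations")
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = _dest_from_freqs(np.asarray([freqs[i], freqs[j]]))
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# geography and Mantel
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (R = 6371 km); broadcasts over arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_geo_distance(table: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distance matrix (km) between populations."""
    lon = table["lon"].to_numpy(float)
    lat = table["lat"].to_numpy(float)
    values = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(labels=table["pop_id"].astype(str).tolist(), values=values)


def mantel_test(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """One-sided (greater) permutation Mantel test.

    Returns ``(r, r_squared, p)`` where ``r`` is the Pearson correlation
    of the lower triangles and
    ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)``.  Permutations
    shuffle rows and columns of the genetic matrix simultaneously.
    """
    if genetic.labels != geographic.labels:
        raise ValueError("distance matrices have mismatched labels")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    x = genetic.values
    y = geographic.condensed()
    iu = np.triu_indices(genetic.n, k=1)

    def corr(mat: np.ndarray) -> float:
        v = mat[iu]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(np.corrcoef(v, y)[0, 1])

    r_obs = corr(x)
    count = 0
    n = genetic.n
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(x[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return r_obs, r_obs**2, p


# ---------------------------------------------------------------------------
# the per-population index table
# ---------------------------------------------------------------------------

def genetic_index_table(
    aflp: AFLPMatrix, haplotypes: HaplotypeData | None = None
) -> pd.DataFrame:
    """Compute all per-population indices into one table.

    Columns: ``pop_id, n, hap_div, nuc_div, gene_div, rarity``.  Indices
    are NaN (flagged undefined) for populations with fewer than two
    sampled individuals.
    """
    rarity = aflp_rarity(aflp)
    rows = []
    hap_groups = haplotypes.populations() if haplotypes is not None else {}
    for pop, bands in sorted(aflp.populations().items()):
        n = bands.shape[0]
        try:
            gene_div = aflp_gene_diversity(bands)
        except UndefinedIndexError:
            gene_div = np.nan
        hap_div = nuc_div = np.nan
        if haplotypes is not None and pop in hap_groups:
            idx = hap_groups[pop]
            seqs = [haplotypes.alignment[i] for i in idx]
            ids = [haplotypes.individuals[i] for i in idx]
            hap_counts = pd.Series(
                [haplotypes.haplotype_id[i] for i in ids]
            ).value_counts()
            indels = (
                haplotypes.indel_characters[idx]
                if haplotypes.indel_characters.size
                else np.zeros((len(idx), 0), dtype=int)
            )
            try:
                hap_div = haplotype_diversity(hap_counts.to_numpy())
                nuc_div = nucleotide_diversity(seqs, indels)
            except UndefinedIndexError:
                pass
        rows.append(
            {
                "pop_id": pop,
                "n": n,
                "hap_div": hap_div,
                "nuc_div": nuc_div,
                "gene_div": gene_div,
                "rarity": rarity.get(pop, np.nan),
            }
        )
    return pd.DataFrame(rows)
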