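"""End-to-end orchestration of the analysis chain.

Stages: genetic indices -> differentiation and isolation by distance ->
grid-correlation refugium inference -> cost distance from the inferred
source margin -> single-predictor GLM screens and three-matrix variation
partitioning.  All outputs land in one directory together with a JSON
manifest recording the configuration hash, seeds and output checksums,
so a rerun with identical inputs is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from refugeo import costdist, glm, io, popgen, refugium
from refugeo import __version__
from refugeo.datatypes import APO_COLUMNS, ECO_COLUMNS

log = logging.getLogger("refugeo")

INDEX_COLUMNS = ("hap_div", "nuc_div", "gene_div", "rarity")


@dataclasses.dataclass
class PipelineConfig:
    """Paths and options for a full run."""

    pops_csv: str
    aflp_csv: str | None = None
    fasta: str | None = None
    dem_asc: str | None = None
    source_geojson: str | None = None
    out_dir: str = "refugeo_out"
    lon_min: float = 9.4
    lat_min: float = 44.7
    lon_max: float = 13.9
    lat_max: float = 48.1
    cell_size: float = 0.1
    family_size_eco: int = 12
    family_size_apo: int = 3
    mantel_permutations: int = 10_000
    seed: int = 1
    skip_genetics: bool = False
    geographic_cost: bool = True

    def validate(self) -> None:
        paths = [self.pops_csv]
        if not self.skip_genetics:
            paths += [p for p in (self.aflp_csv, self.fasta) if p]
        paths += [p for p in (self.dem_asc, self.source_geojson) if p]
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def read_aflp_csv(path: str | Path):
    """Read an individual x locus band matrix CSV.

    Expected columns: ``individual``, ``pop_id``, then one 0/1 column per
    locus.
    """
    from refugeo.datatypes import AFLPMatrix

    df = pd.read_csv(path)
    for col in ("individual", "pop_id"):
        if col not in df.columns:
            raise io.FormatError(f"AFLP matrix missing column {col!r}")
    loci = [c for c in df.columns if c not in ("individual", "pop_id")]
    return AFLPMatrix(
        individuals=df["individual"].astype(str).tolist(),
        pop_of=dict(zip(df["individual"].astype(str), df["pop_id"].astype(str))),
        bands=df[loci].to_numpy(int),
    )


def write_aflp_csv(path: str | Path, aflp) -> None:
    df = pd.DataFrame(aflp.bands, columns=[f"L{k + 1}" for k in range(aflp.n_loci)])
    df.insert(0, "pop_id", [aflp.pop_of[i] for i in aflp.individuals])
    df.insert(0, "individual", aflp.individuals)
    df.to_csv(path, index=False)


def haplotypes_from_fasta(fasta: str | Path, pop_of: dict[str, str]):
    """Build HaplotypeData from an aligned FASTA and an individual->pop map."""
    from refugeo.datatypes import HaplotypeData

    ids, seqs = io.read_fasta(fasta)
    unknown = [i for i in ids if i not in pop_of]
    if unknown:
        raise ValueError(f"FASTA individuals without population mapping: {unknown[:5]}")
    return HaplotypeData(individuals=ids, pop_of=pop_of, alignment=seqs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns a result summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"version": __version__, "seed": config.seed}
    pops = io.read_population_table(config.pops_csv)

    grid = refugium.build_grid(
        config.lon_min, config.lat_min, config.lon_max, config.lat_max, config.cell_size
    )

    if not config.skip_genetics:
        if not (config.aflp_csv and config.fasta):
            raise ValueError("genetics stage needs --aflp and --fasta (or --skip-genetics)")
        aflp = read_aflp_csv(config.aflp_csv)
        haps = haplotypes_from_fasta(config.fasta, aflp.pop_of)
        indices = popgen.genetic_index_table(aflp, haps)
        io.write_csv(out / "indices.csv", indices)

        dest = popgen.jost_dest(aflp)
        gen_dm = popgen.pairwise_dest(aflp)
        geo_all = popgen.pairwise_geo_distance(pops.set_index("pop_id").loc[gen_dm.labels].reset_index())
        r, r2, p_mantel = popgen.mantel_test(
            gen_dm, geo_all, n_perm=config.mantel_permutations, seed=config.seed
        )
        results["dest"] = dest
        results["mantel"] = {"r": r, "r2": r2, "p": p_mantel}
        (out / "structure.json").write_text(
            json.dumps({"dest": dest, "mantel_r": r, "mantel_r2": r2, "mantel_p": p_mantel}, indent=2)
        )

        geno_pops = pops.set_index("pop_id").loc[indices["pop_id"]].reset_index()
        rank_surfaces = []
        for idx_name in INDEX_COLUMNS:
            surf = refugium.correlation_surface(
                grid, geno_pops, indices[idx_name].to_numpy(), index_name=idx_name
            )
            io.write_raster(out / f"corr_{idx_name}.asc", refugium.surface_to_raster(surf))
            rank_surfaces.append(refugium.rank_cells(surf))
        combined = refugium.combine_ranks(rank_surfaces)
        io.write_raster(out / "combined_rank.asc", refugium.surface_to_raster(combined))
        direction = refugium.direction_test(combined)
        direction_pop = refugium.direction_test(combined, pops=geno_pops, variant="population")
        results["direction"] = dataclasses.asdict(direction)
        results["direction_population_variant"] = dataclasses.asdict(direction_pop)
        (out / "direction.json").write_text(
            json.dumps(
                {
                    "cell": dataclasses.asdict(direction),
                    "population": dataclasses.asdict(direction_pop),
                },
                indent=2,
            )
        )

    if config.dem_asc and config.source_geojson:
        dem = io.read_raster(config.dem_asc)
        margin = io.read_geojson_line(config.source_geojson)
        source = costdist.rasterize_source(margin, dem)
        surface = costdist.accumulate_cost(dem, source, geographic=config.geographic_cost)
        io.write_raster(out / "cost_surface.asc", surface.raster)
        pops = costdist.extract_cost(surface, pops)
        io.write_csv(out / "pops_with_cost.csv", pops)

    if "cost_distance" in pops.columns:
        prep = io.prepare_predictors(pops)
        y = pops.loc[prep.kept_index, "present_4x"].to_numpy()
        screen_cols = pd.concat([prep.eco, prep.hist], axis=1)
        screen_all = pd.concat([screen_cols, prep.apo], axis=1)
        screen = glm.single_predictor_screen(y, screen_all, family_size=config.family_size_eco)
        io.write_csv(out / "screen_table.csv", screen)
        fractions = glm.varpart3(y, prep.eco, prep.hist, prep.apo)
        (out / "fractions.json").write_text(
            json.dumps(
                {**fractions.as_dict(), "adj_d2_full": fractions.adj_d2_full}, indent=2
            )
        )
        cross = glm.apomict_cross_occurrence(pops, family_size=config.family_size_apo)
        io.write_csv(out / "cross_occurrence.csv", cross)
        results["varpart"] = fractions.as_dict()
        results["screen"] = screen.to_dict(orient="records")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def eco_columns() -> tuple[str, ...]:
    return ECO_COLUMNS


def apo_columns() -> tuple[str, ...]:
    return APO_COLUMNS
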