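"""End-to-end orchestration: simulate fixtures, filter, population genetics,
dispersal simulation, and isolation-by-distance, with a manifest of
parameters, seeds and input checksums."""
from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ibd as ibd_mod
from . import popgen
from .dispersal import (
    ConnectivityMatrix, CurrentField, HabitatGrid, advect, aggregate_regions,
    average_years, build_connectivity, build_schedule, iterate_generations,
    schedule_frame,
)
from .genotypes import (
    exclude_loci, filter_lineage, filter_populations, read_genepop,
    read_metadata, read_qmatrix, write_genepop, write_metadata, write_qmatrix,
)
from .synthetic import (
    SimGenotypeConfig, SimOceanConfig, generate_genotypes, generate_moon_table,
    generate_ocean, true_qmatrix,
)

log = logging.getLogger("coralconnect")


@dataclass
class Thresholds:
    lineage_membership: float = 0.70
    min_mlg: int = 9
    pid: float = 0.001
    assignment: float = 0.70
    alpha: float = 0.05


@dataclass
class SimParams:
    t_base: float = 13.0
    dd_threshold: float = 1000.0
    window_days: int = 10
    offset_days: int = 3
    particles_per_day: int = 50
    pld_max: float = 42.0
    competency_min: float = 3.0
    dt_hours: float = 2.0
    years: list[int] = field(default_factory=lambda: [2001, 2002, 2003, 2004])
    n_generations: int = 1000


@dataclass
class RunConfig:
    """Paths, thresholds and simulation parameters for a pipeline run.

    All paper-default thresholds are embedded and overridable; missing paths
    make the dependent stage fail fast with the stage name.
    """

    genotypes: str | None = None
    metadata: str | None = None
    qmatrix_k2: str | None = None
    qmatrix_k3: str | None = None
    field_file: str | None = None
    habitat: str | None = None
    sst: str | None = None
    moons: str | None = None
    excluded_loci: list[str] = field(default_factory=list)
    target_cluster: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    sim: SimParams = field(default_factory=SimParams)
    n_perm_fst: int = 999
    n_perm_amova: int = 999
    n_resamples_exact: int = 2000
    n_perm_mantel: int = 10_000
    ibd_exclude: list[str] = field(default_factory=list)
    seed: int = 0
    simulate: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        sim = SimParams(**raw.pop("sim", {}))
        return cls(thresholds=thr, sim=sim, **raw)

    def validate(self, stages: list[str]) -> None:
        need = {
            "filter": ["genotypes"],
            "popgen": ["genotypes"],
            "dispersal": ["field_file", "habitat", "sst", "moons"],
            "ibd": ["genotypes", "habitat"],
        }
        for stage in stages:
            for key in need.get(stage, []):
                if not self.simulate and getattr(self, key) is None:
                    raise ValueError(
                        f"stage {stage!r} requires config path {key!r}"
                    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: RunConfig, outdir, seed: int | None = None,
        stages: tuple[str, ...] = ("simulate", "filter", "popgen",
                                   "dispersal", "ibd")) -> Path:
    """Execute the requested stages; returns the run directory.

    Writes a manifest (parameters, seeds, checksums, stage timings); each
    stage reads only its declared inputs and never rewrites another stage's
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    rng_seeds = {
        name: int(s)
        for name, s in zip(
            ("simulate", "popgen", "dispersal", "ibd"),
            np.random.SeedSequence(seed).generate_state(4) % (2 ** 31),
        )
    }
    config.validate([s for s in stages if s != "simulate"])
    manifest: dict = {
        "seed": seed, "stage_seeds": rng_seeds, "stages": list(stages),
        "config": asdict(config), "timings_s": {}, "checksums": {},
        "parameter_sources": {
            "lineage_membership=0.70": "membership >= 70% in both K blocks",
            "min_mlg=9": "populations with >= 9 MLGs retained",
            "pid=0.001": "clone flag at probability of identity < 0.001",
            "assignment=0.70": "assigned when top probability > 70%",
            "t_base=13,dd_threshold=1000,start=Feb 1":
                "degree-day spawning rule, integral max(T-13,0) dt >= 1000",
            "offset=3,window=10,particles_per_day=50":
                "release 3 days before full moon, 10 days, 50/day",
            "pld_max=42,competency_min=3":
                "42-day pelagic duration, settlement from day 3",
        },
    }

    paths = {
        "genotypes": outdir / "genotypes.gen",
        "metadata": outdir / "metadata.csv",
        "q2": outdir / "qmatrix_k2.txt",
        "q3": outdir / "qmatrix_k3.txt",
        "field": outdir / "field.nc",
        "habitat": outdir / "habitat.csv",
        "sst": outdir / "sst.csv",
        "moons": outdir / "moons.csv",
    }

    def timed(name):
        class _T:
            def __enter__(self):
                self.t = _time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, *exc):
                manifest["timings_s"][name] = round(
                    _time.perf_counter() - self.t, 3
                )
                log.info("stage %s finished in %.1fs", name,
                         manifest["timings_s"][name])
        return _T()

    # ---------------- simulate ------------------------------------------
    if "simulate" in stages and config.simulate:
        with timed("simulate"):
            _simulate_fixtures(config, paths, rng_seeds["simulate"])
        config.genotypes = str(paths["genotypes"])
        config.metadata = str(paths["metadata"])
        config.qmatrix_k2 = str(paths["q2"])
        config.qmatrix_k3 = str(paths["q3"])
        config.field_file = str(paths["field"])
        config.habitat = str(paths["habitat"])
        config.sst = str(paths["sst"])
        config.moons = str(paths["moons"])

    for key in ("genotypes", "metadata", "qmatrix_k2", "qmatrix_k3",
                "field_file", "habitat", "sst", "moons"):
        p = getattr(config, key)
        if p and Path(p).exists():
            manifest["checksums"][key] = _sha256(Path(p))

    table = None
    # ---------------- filter --------------------------------------------
    if "filter" in stages:
        with timed("filter"):
            if config.genotypes is None:
                raise ValueError("stage 'filter' requires a genotypes path")
            table = read_genepop(config.genotypes)
            if config.metadata:
                table = table.with_metadata(read_metadata(config.metadata))
            if config.excluded_loci:
                table = exclude_loci(table, config.excluded_loci)
            reports = []
            qblocks = {}
            if config.qmatrix_k2:
                qblocks[2] = read_qmatrix(config.qmatrix_k2)
            if config.qmatrix_k3:
                qblocks[3] = read_qmatrix(config.qmatrix_k3)
            if qblocks:
                table, rep = filter_lineage(
                    table, qblocks, config.target_cluster,
                    config.thresholds.lineage_membership,
                )
                reports.append(rep.to_frame())
            table, clones = popgen.remove_clones(table, config.thresholds.pid)
            table, rep = filter_populations(table, config.thresholds.min_mlg)
            reports.append(rep.to_frame())
            pd.concat(reports).to_csv(outdir / "filter_report.csv", index=False)
            pd.DataFrame(
                [
                    (p, len(clones.genets.get(p, [])), clones.clonal_fraction.get(p))
                    for p in clones.clonal_fraction
                ],
                columns=["population", "n_mlg", "clonal_fraction"],
            ).to_csv(outdir / "clonality.csv", index=False)
            write_genepop(table, outdir / "filtered.gen")
            write_metadata(table, outdir / "filtered_metadata.csv")

    # ---------------- popgen --------------------------------------------
    if "popgen" in stages:
        with timed("popgen"):
            if table is None:
                table = read_genepop(config.genotypes)
                if config.metadata:
                    table = table.with_metadata(read_metadata(config.metadata))
            sseed = rng_seeds["popgen"]
            div = popgen.diversity(table)
            div.means.to_csv(outdir / "diversity.csv")
            fst, fst_p = popgen.pairwise_fst(table, n_perm=config.n_perm_fst,
                                             seed=sseed)
            fst.to_csv(outdir / "pairwise_fst.csv")
            if fst_p is not None:
                fst_p.to_csv(outdir / "pairwise_fst_p.csv")
            popgen.jost_dest(table).to_csv(outdir / "pairwise_dest.csv")
            theta, p_global = popgen.global_fst(
                table, n_perm=config.n_perm_amova, seed=sseed + 1
            )
            amova_rows = [
                {"scenario": "global", "FST": theta, "p_FST": p_global}
            ]
            region_groups = dict(table.region)
            if len(set(region_groups.values())) > 1:
                scenarios = {
                    "temperate_vs_subtropical": {
                        p: ("subtropical" if r == "subtropical" else "temperate")
                        for p, r in region_groups.items()
                    },
                    "recent_vs_pre_existing_temperate": {
                        p: r for p, r in region_groups.items()
                        if r != "subtropical"
                    },
                }
                for name, grouping in scenarios.items():
                    pops_in = [p for p in table.pop_names if p in grouping]
                    if len(set(grouping[p] for p in pops_in)) < 2:
                        continue
                    idx = np.concatenate(
                        [table.pop_indices(p) for p in pops_in]
                    )
                    sub = table.take_individuals(np.sort(idx))
                    res = popgen.amova(sub, grouping,
                                       n_perm=config.n_perm_amova,
                                       seed=sseed + 2)
                    amova_rows.append({
                        "scenario": name,
                        **{f"pct_{k}": v for k, v in res.percentages.items()},
                        **{k: v for k, v in res.indices.items()},
                        **{f"p_{k}": v for k, v in res.pvalues.items()},
                    })
            pd.DataFrame(amova_rows).to_csv(outdir / "amova.csv", index=False)

            # pairwise exact tests + Holm flags
            pops = table.pop_names
            rows = []
            for i in range(len(pops)):
                for j in range(i + 1, len(pops)):
                    res = popgen.exact_differentiation_test(
                        table, (pops[i], pops[j]),
                        n_resamples=config.n_resamples_exact, seed=sseed + 3,
                    )
                    rows.append((pops[i], pops[j], res.combined_p))
            exact_df = pd.DataFrame(rows, columns=["pop_a", "pop_b", "p"])
            exact_df["significant_holm"] = popgen.sequential_bonferroni(
                exact_df["p"].to_numpy(), config.thresholds.alpha
            )
            exact_df.to_csv(outdir / "exact_tests.csv", index=False)

            assign = popgen.assign_individuals(
                table, config.thresholds.assignment
            )
            assign.to_csv(outdir / "assignment.csv")
            ord_res = popgen.pcoa(fst, n_axes=2)
            ord_res.coordinates.to_csv(outdir / "pcoa.csv")
            if len(pops) >= 3:
                treeres = popgen.nei_nj_tree(table, n_bootstrap=200,
                                             seed=sseed + 4)
                (outdir / "nj_tree.nwk").write_text(treeres.newick + "\n")

    # ---------------- dispersal -----------------------------------------
    C_iter = None
    habitat = None
    if "dispersal" in stages:
        with timed("dispersal"):
            field_obj = CurrentField.from_netcdf(config.field_file)
            habitat = HabitatGrid.read_csv(config.habitat)
            sst = pd.read_csv(config.sst, index_col=0, parse_dates=True)
            moons = pd.DatetimeIndex(
                pd.read_csv(config.moons)["full_moon"].map(pd.Timestamp)
            )
            entries, skipped = build_schedule(
                sst, moons, config.sim.years,
                t_base=config.sim.t_base,
                threshold=config.sim.dd_threshold,
                offset_days=config.sim.offset_days,
                window_days=config.sim.window_days,
                particles_per_day=config.sim.particles_per_day,
            )
            schedule_frame(entries).to_csv(outdir / "schedule.csv", index=False)
            yearly = []
            for year in config.sim.years:
                year_entries = [e for e in entries if e.year == year]
                fates = advect(
                    field_obj, year_entries, habitat,
                    pld_max=config.sim.pld_max,
                    competency_min=config.sim.competency_min,
                    dt_hours=config.sim.dt_hours,
                    seed=rng_seeds["dispersal"] + year,
                )
                released = {
                    e.site: e.total_particles for e in year_entries
                }
                for s in habitat.site_names:
                    released.setdefault(s, 0)
                C = build_connectivity(fates, habitat.site_names, released,
                                       year=year)
                C.to_csv(outdir / f"connectivity_{year}.csv")
                yearly.append(C)
            C_mean = average_years(yearly)
            C_mean.to_csv(outdir / "connectivity_mean.csv")
            C_iter, trace = iterate_generations(
                C_mean, n_gen=config.sim.n_generations, tol=1e-9
            )
            C_iter.to_csv(outdir / "connectivity_iterated.csv")
            pd.Series(trace, name="max_change").to_csv(
                outdir / "iteration_trace.csv", index_label="generation"
            )
            aggregate_regions(C_iter, habitat.region_map).to_csv(
                outdir / "connectivity_regions.csv"
            )

    # ---------------- ibd ------------------------------------------------
    if "ibd" in stages:
        with timed("ibd"):
            if table is None:
                table = read_genepop(config.genotypes)
                if config.metadata:
                    table = table.with_metadata(read_metadata(config.metadata))
            fst_mat = popgen.pairwise_fst(table)[0]
            coords = pd.DataFrame(
                {
                    "lat": {p: table.coords[p][0] for p in table.pop_names},
                    "lon": {p: table.coords[p][1] for p in table.pop_names},
                }
            )
            gc = ibd_mod.great_circle_matrix(coords)
            predictors = {"euclidean": gc}
            if config.field_file and Path(config.field_file).exists():
                field_obj = CurrentField.from_netcdf(config.field_file)
                predictors["oceanographic"] = ibd_mod.sea_path_matrix(
                    coords, field_obj.mask, field_obj.lat, field_obj.lon
                )
            if C_iter is not None and habitat is not None:
                # map populations onto habitat sites by order when they match
                if set(table.pop_names).issubset(set(C_iter.sites)):
                    predictors["simulated_larvae"] = (
                        ibd_mod.connectivity_distance(C_iter)
                        .submatrix(table.pop_names)
                    )
            rows = []
            for name, mat in predictors.items():
                res = ibd_mod.mantel(
                    fst_mat, mat, n_perm=config.n_perm_mantel,
                    exclude=config.ibd_exclude, seed=rng_seeds["ibd"],
                )
                rows.append((name, res.r, res.p, res.n_permutations))
                keep = [p for p in table.pop_names
                        if p not in set(config.ibd_exclude)]
                sub_g = fst_mat.submatrix(keep)
                sub_x = mat.submatrix(keep)
                iu = np.triu_indices(len(keep), k=1)
                pd.DataFrame({
                    "pop_a": [keep[a] for a in iu[0]],
                    "pop_b": [keep[b] for b in iu[1]],
                    "distance": sub_x.values[iu],
                    "fst": sub_g.values[iu],
                }).to_csv(outdir / f"ibd_scatter_{name}.csv", index=False)
            pd.DataFrame(
                rows, columns=["predictor", "mantel_r", "p", "n_perm"]
            ).to_csv(outdir / "ibd_mantel.csv", index=False)

    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(
        yaml.safe_dump(json.loads(json.dumps(manifest, default=str)),
                       sort_keys=False)
    )
    return outdir


def _simulate_fixtures(config: RunConfig, paths: dict, seed: int) -> None:
    """Write the full synthetic input set into the run directory."""
    # study-like regime: a linear stepping-stone chain south -> north, clonal
    # replication in the recently expanded northern populations, and cryptic-
    # lineage admixture among subtropical individuals
    from .synthetic import LineageSpec

    admix = {p: [0.0] * 20 for p in ("P01", "P02", "P03")}
    for p in admix:
        for i in range(6):
            admix[p][i] = 0.9
        for i in range(6, 12):
            admix[p][i] = 0.1
    gcfg = SimGenotypeConfig(
        layout="linear-stepping-stone",
        clone_spec={"P13": [11], "P12": [4]},
        lineage_spec=LineageSpec(divergence=0.3, admixture=admix),
        missing_rate=0.01,
        seed=seed,
    )
    table = generate_genotypes(gcfg)
    write_genepop(table, paths["genotypes"])
    write_metadata(table, paths["metadata"])
    q = true_qmatrix(table)
    write_qmatrix(q[2], paths["q2"])
    write_qmatrix(q[3], paths["q3"])

    sites = pd.DataFrame(
        [
            (p, table.coords[p][0], table.coords[p][1],
             {"subtropical": "A", "pre_existing_temperate": "B",
              "recent_temperate": "C"}[table.region[p]])
            for p in table.pop_names
        ],
        columns=["site", "lat", "lon", "region"],
    )
    years = config.sim.years
    ocfg = SimOceanConfig(
        t0=date(min(years), 1, 1),
        n_days=int(365.25 * (max(years) - min(years) + 1)) + 60,
        cell_deg=1.0 / 12.0,
        jet_path=tuple(
            (float(lat), float(lon))
            for lat, lon in zip(sites["lat"], sites["lon"])
        ),
        seed=seed + 1,
    )
    field_obj, sst = generate_ocean(ocfg, sites)
    CurrentField(field_obj).to_netcdf(paths["field"])
    HabitatGrid(sites).to_csv(paths["habitat"])
    sst.to_csv(paths["sst"], index_label="date")
    moons = generate_moon_table(
        date(min(years), 1, 1), date(max(years) + 1, 3, 1),
        date(min(years), 1, 9),
    )
    pd.DataFrame({"full_moon": moons}).to_csv(paths["moons"], index=False)
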