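"""End-to-end orchestration: per-species analysis and report bundle.

For each species: wing selection, GPA, tangent distances and centroid sizes,
population metrics (mD/md/wsD/wsM, genetic mismatch and nucleotide
diversity), diversity and differentiation surfaces at each distance-weighting
exponent, cross-species diversity correlations at the combined sampling
localities, the two-stage MRDM-CA (inter-population responses) and LR-CA
(intra-population responses), and a pooled-alignment PCoA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import landmark_io, popmetrics, regression, shape, surfaces
from .core import DistanceMatrix
from .popmetrics import LocusAlignmentSet, PopulationAssignment
from .regression import PredictorSet
from .surfaces import InterpolationSettings

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_analysis"]


@dataclass
class AnalysisConfig:
    tps_path: str
    specimen_csv: str
    fasta_dir: str | None = None
    species: list[str] | None = None  # None = all species in the table
    a_values: tuple[float, ...] = (1.0, 5.0, 10.0)
    resolution_arcmin: float = 10.0
    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05
    suppressor_tau: float = 0.1
    out_dir: str = "morphoscape_out"
    pooled_gpa: bool = False  # single alignment across species for everything
    write_surfaces: bool = True


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _population_frame(records, pop_ids):
    rows = {}
    for r in records:
        if r.population_id not in rows:
            rows[r.population_id] = r
    return {p: rows[p] for p in pop_ids if p in rows}


def _species_analysis(
    species: str,
    configs,
    records,
    loci: LocusAlignmentSet | None,
    cfg: AnalysisConfig,
    out_dir: Path,
) -> dict:
    result: dict = {"species": species}
    record_map = {r.specimen_id: r for r in records}
    configs = [c for c in configs if c.specimen_id in record_map]

    with _stage("wing_selection"):
        selected = landmark_io.select_wing_per_specimen(configs)
    result["n_specimens"] = len(selected)

    with _stage("gpa"):
        aligned = shape.gpa_align(selected)
        slope, corr = shape.tangent_space_check(aligned)
        tangent_d = shape.tangent_distance_matrix(aligned)
        result["gpa"] = {
            "iterations": aligned.iterations,
            "converged": aligned.converged,
            "tangent_slope": slope,
            "tangent_correlation": corr,
        }

    pops = PopulationAssignment(
        {sid: record_map[sid].population_id for sid in aligned.specimen_ids}
    )
    cs = dict(zip(aligned.specimen_ids, aligned.centroid_sizes))

    with _stage("population_metrics"):
        mD = popmetrics.aggregate_between_populations(tangent_d, pops)
        mD.metric_name = "mD"
        md = popmetrics.within_population_diversity(tangent_d, pops)
        cs_diff = popmetrics.pairwise_absolute_difference(cs, "cs_difference")
        wsD = popmetrics.aggregate_between_populations(cs_diff, pops)
        wsD.metric_name = "wsD"
        wsM = popmetrics.population_mean_size(cs, pops)

    genetic_ok = loci is not None and loci.loci
    iid2_pop = None
    pi: dict[str, float] = {}
    if genetic_ok:
        with _stage("genetic_metrics"):
            sequenced = set(loci.individuals()) & set(aligned.specimen_ids)
            sub = LocusAlignmentSet(
                {
                    name: {i: s for i, s in seqs.items() if i in sequenced}
                    for name, seqs in loci.loci.items()
                }
            )
            if len(sub.individuals()) >= 2:
                iid2 = popmetrics.sequence_mismatch_matrix(sub)
                gpops = PopulationAssignment(
                    {i: pops.mapping[i] for i in iid2.labels}
                )
                iid2_pop = popmetrics.aggregate_between_populations(iid2, gpops)
                iid2_pop.metric_name = "IID2"
                pi = popmetrics.nucleotide_diversity(sub, gpops)
    else:
        logger.warning(
            "species %s: no sequence data; genetic predictors skipped", species
        )

    pop_ids = mD.labels
    pop_records = _population_frame(records, pop_ids)
    coords = {p: (pop_records[p].longitude, pop_records[p].latitude) for p in pop_ids}
    covariates = {
        "elevation": {p: pop_records[p].elevation for p in pop_ids},
        "temperature": {p: pop_records[p].temperature for p in pop_ids},
        "precipitation": {p: pop_records[p].precipitation for p in pop_ids},
    }
    table = popmetrics.build_population_table(pops, coords, md, wsM, pi, covariates)
    result["population_table"] = table

    with _stage("distance_predictors"):
        geo = surfaces.great_circle_matrix([coords[p] for p in pop_ids], pop_ids)
        env_mats = {
            f"{name}_difference": popmetrics.pairwise_absolute_difference(
                vals, f"{name}_difference"
            ).submatrix(pop_ids)
            for name, vals in covariates.items()
        }

    if cfg.write_surfaces:
        with _stage("surfaces"):
            result["surfaces"] = _build_surfaces(
                species, pop_ids, coords, geo, mD, wsD, iid2_pop, md, wsM, pi,
                cfg, out_dir,
            )

    # -- two-stage MRDM-CA (inter-population responses) --
    result["regressions"] = {}
    if len(pop_ids) >= 4:
        mrdm_preds_common: dict[str, DistanceMatrix] = {
            "geographic_distance": geo,
            **env_mats,
        }
        if iid2_pop is not None and set(iid2_pop.labels) == set(pop_ids):
            mrdm_preds_common["genetic_distance"] = iid2_pop.submatrix(pop_ids)
        for resp, other in (("mD", wsD), ("wsD", mD)):
            with _stage(f"mrdm_{resp}"):
                response = mD if resp == "mD" else wsD
                preds = {
                    ("size_difference" if resp == "mD" else "shape_distance"): other,
                    **mrdm_preds_common,
                }
                ps = PredictorSet.from_distance_matrices(
                    response, preds, response_name=resp
                )
                initial, final = regression.two_stage_analysis(
                    ps, n_perm=cfg.n_perm, seed=cfg.seed, tau=cfg.suppressor_tau
                )
                result["regressions"][resp] = (initial, final)
    else:
        logger.warning(
            "species %s: fewer than 4 populations; MRDM skipped", species
        )

    # -- two-stage LR-CA (intra-population responses) --
    lr_base = ["longitude", "latitude", "elevation", "temperature", "precipitation"]
    if pi:
        lr_base.insert(2, "pi")
    for resp, other in (("md", "wsM"), ("wsM", "md")):
        predictors = [other] + lr_base
        usable = table[[resp] + predictors].dropna()
        if len(usable) < len(predictors) + 2:
            logger.warning(
                "species %s: too few populations with %s for LR-CA; skipped",
                species,
                resp,
            )
            continue
        with _stage(f"lr_{resp}"):
            ps = PredictorSet.from_table(table, resp, predictors)
            initial, final = regression.two_stage_analysis(
                ps, tau=cfg.suppressor_tau
            )
            result["regressions"][resp] = (initial, final)
    return result


def _build_surfaces(
    species, pop_ids, coords, geo, mD, wsD, iid2_pop, md, wsM, pi, cfg, out_dir
) -> dict:
    """GDivPAL-style diversity surfaces at population locations and
    GDisPAL-style differentiation surfaces of residual distances at Delaunay
    edge midpoints, one raster per metric per exponent."""
    surf_dir = out_dir / "surfaces"
    surf_dir.mkdir(parents=True, exist_ok=True)
    points = [coords[p] for p in pop_ids]
    manifest = {}

    diversity_metrics = {"md": md, "wsM": wsM}
    if pi:
        diversity_metrics["pi"] = pi
    differentiation_metrics = {"mD": mD, "wsD": wsD}
    if iid2_pop is not None:
        differentiation_metrics["IID2"] = iid2_pop

    mids = None
    if len(points) >= 3:
        try:
            mids = surfaces.delaunay_edge_midpoints(points)
        except ValueError as exc:
            logger.warning("species %s: no Delaunay network (%s)", species, exc)

    for a in cfg.a_values:
        settings = InterpolationSettings(a=a, resolution_arcmin=cfg.resolution_arcmin)
        for name, values in diversity_metrics.items():
            pts = [
                (*coords[p], values[p]) for p in pop_ids if p in values
            ]
            if not pts:
                continue
            surf = surfaces.idw_surface(pts, settings)
            path = surf_dir / f"{species}_{name}_a{a:g}.asc"
            surf.write_ascii_grid(path)
            manifest[f"{name}_a{a:g}"] = str(path)
        if mids is None:
            continue
        for name, dm in differentiation_metrics.items():
            dm_o = dm.submatrix(pop_ids)
            resid = surfaces.residual_distances(dm_o, geo)
            pts = [
                (mlon, mlat, resid.values[i, j]) for (i, j), (mlon, mlat) in mids
            ]
            surf = surfaces.idw_surface(pts, settings)
            path = surf_dir / f"{species}_{name}_resid_a{a:g}.asc"
            surf.write_ascii_grid(path)
            manifest[f"{name}_resid_a{a:g}"] = str(path)
    return manifest


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run the whole pipeline; returns the report bundle (also written to disk)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("read_inputs"):
        configs = landmark_io.read_tps(cfg.tps_path)
        records = landmark_io.read_specimen_table(cfg.specimen_csv)
        matched, table_only, lm_only = landmark_io.match_specimens(records, configs)
        loci = (
            popmetrics.read_locus_fasta_dir(cfg.fasta_dir)
            if cfg.fasta_dir and Path(cfg.fasta_dir).is_dir()
            else None
        )

    species_list = cfg.species or sorted({r.species for r in records})
    bundle: dict = {
        "selection": {
            "n_matched": len(matched),
            "table_only": table_only,
            "landmarks_only": lm_only,
        },
        "species": {},
    }
    for sp in species_list:
        sp_records = [r for r in records if r.species == sp]
        sp_ids = {r.specimen_id for r in sp_records}
        sp_configs = [c for c in configs if c.specimen_id in sp_ids]
        if not sp_configs:
            logger.warning("species %s: no landmark data; skipped", sp)
            continue
        bundle["species"][sp] = _species_analysis(
            sp, sp_configs, sp_records, loci, cfg, out_dir
        )

    # cross-species diversity correlations at the combined localities (a = 5)
    bundle["cross_species_md"] = _cross_species_md(bundle, records, cfg)

    # pooled PCoA over all species
    with _stage("pooled_pcoa"):
        record_map = {r.specimen_id: r for r in records}
        pooled_configs = [c for c in configs if c.specimen_id in record_map]
        selected = landmark_io.select_wing_per_specimen(pooled_configs)
        if len(selected) >= 3:
            pooled = shape.gpa_align(selected)
            d = shape.tangent_distance_matrix(pooled)
            n_axes = min(2, d.n - 1)
            coords_pcoa, eigvals = shape.pcoa(d, n_axes)
            pcoa_df = pd.DataFrame(
                coords_pcoa,
                index=d.labels,
                columns=[f"axis{i + 1}" for i in range(coords_pcoa.shape[1])],
            )
            pcoa_df["species"] = [record_map[s].species for s in d.labels]
            pcoa_df.to_csv(out_dir / "pcoa_pooled.csv")
            np.savetxt(out_dir / "pcoa_eigenvalues.csv", eigvals, delimiter=",")
            bundle["pcoa"] = {"eigenvalues": eigvals.tolist()}

    _write_reports(bundle, out_dir)
    return bundle


def _cross_species_md(bundle: dict, records, cfg: AnalysisConfig) -> dict:
    """Pairwise species correlations of md surfaces extracted at the combined
    set of sampling localities."""
    from .surfaces import extract_at_points, idw_surface

    locs: list[tuple[float, float]] = []
    for r in records:
        pt = (round(r.longitude, 6), round(r.latitude, 6))
        if pt not in locs:
            locs.append(pt)
    per_species: dict[str, np.ndarray] = {}
    for sp, res in bundle["species"].items():
        table = res.get("population_table")
        if table is None:
            continue
        sub = table.dropna(subset=["md"])
        if len(sub) == 0:
            continue
        pts = list(zip(sub["longitude"], sub["latitude"], sub["md"]))
        lon_min = min(p[0] for p in locs + pts)
        lon_max = max(p[0] for p in locs + pts)
        lat_min = min(p[1] for p in locs + pts)
        lat_max = max(p[1] for p in locs + pts)
        settings = InterpolationSettings(
            a=5.0,
            resolution_arcmin=cfg.resolution_arcmin,
            extent=(lon_min - 1, lon_max + 1, lat_min - 1, lat_max + 1),
        )
        surf = idw_surface(pts, settings)
        per_species[sp] = extract_at_points(surf, locs)
    out = {}
    names = sorted(per_species)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            try:
                r, r2, p = surfaces.surface_correlation(
                    per_species[names[i]], per_species[names[j]]
                )
                out[f"{names[i]}|{names[j]}"] = {"r": r, "r_squared": r2, "p": p}
            except ValueError as exc:
                logger.warning(
                    "cross-species correlation %s/%s skipped: %s",
                    names[i],
                    names[j],
                    exc,
                )
    return out


def _write_reports(bundle: dict, out_dir: Path) -> None:
    reports_dir = out_dir / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    serializable: dict = {
        "selection": bundle["selection"],
        "cross_species_md": bundle.get("cross_species_md", {}),
        "species": {},
    }
    for sp, res in bundle["species"].items():
        entry: dict = {
            "n_specimens": res["n_specimens"],
            "gpa": res["gpa"],
            "surfaces": res.get("surfaces", {}),
            "regressions": {},
        }
        res["population_table"].to_csv(reports_dir / f"{sp}_population_table.csv")
        for resp, (initial, final) in res.get("regressions", {}).items():
            entry["regressions"][resp] = {
                "initial": initial.to_dict(),
                "final": final.to_dict(),
            }
            final.to_dataframe().to_csv(
                reports_dir / f"{sp}_{resp}_final.csv", index=False
            )
            initial.to_dataframe().to_csv(
                reports_dir / f"{sp}_{resp}_initial.csv", index=False
            )
        serializable["species"][sp] = entry
    (reports_dir / "bundle.json").write_text(json.dumps(serializable, indent=1))
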