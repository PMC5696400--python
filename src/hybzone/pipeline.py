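"""End-to-end orchestration of the contact-zone analysis.

One :class:`RunConfig` drives: data loading (or synthetic-zone simulation)
-> reference pooling -> ML hybrid indices and classification -> regional
admixture summaries -> pairwise hybrid-proportion randomization tests with
sequential Bonferroni -> maternal-asymmetry binomial tests -> Fst/Rst
matrices -> PCoA -> Mantel IBD and the sympatry-residual randomization ->
acoustic regressions and RCD summaries.  All outputs are CSV/JSON files in
the configured output directory plus a run log recording seeds and stage
order; a fixed master seed makes every numeric output reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustics as ac
from . import asymmetry as asym
from . import genotypes as gio
from . import popstructure as ps
from . import resampling as rs
from .hindex import HybridIndexEstimator, summarize_regions
from .simulate import SimConfig, sim_zone

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs before it are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat, JSON-compatible configuration of one pipeline run."""

    outdir: str = "hybzone_out"
    seed: int = 0
    # data source: either a simulation or input files
    simulate: bool = True
    sim: SimConfig | None = None
    genepop_path: str | None = None
    meta_path: str | None = None
    maternal_path: str | None = None
    calls_path: str | None = None
    # analysis settings
    ref_selector_a: dict = field(
        default_factory=lambda: {"species": "A", "sympatry": "allopatric"}
    )
    ref_selector_b: dict = field(
        default_factory=lambda: {"species": "B", "sympatry": "allopatric"}
    )
    alpha_smoothing: float = 0.5
    f1_bounds: tuple[float, float] = (0.25, 0.75)
    exclude_loci: tuple[str, ...] = ()
    min_region_n: int = 30
    pair_reps: int = 100_000
    sidedness: str = "two_sided"
    test_alpha: float = 0.05
    min_n_fst: int = 5
    mantel_perms: int = 10_000
    ibd_reps: int = 200

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if raw.get("sim"):
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)


def _stage(name, log, func):
    t0 = time.perf_counter()
    try:
        out = func()
    except Exception as exc:  # halt with a stage-named error
        log["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
        raise PipelineStageError(name, exc) from exc
    log["stages"].append(
        {"stage": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
    )
    logger.info("stage %s done (%.2fs)", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns a dict of the in-memory results (DataFrames and result
    objects), keyed by stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ["sim", "pairs_f1", "pairs_ci", "ibd_a", "ibd_b", "diversity"],
            master.spawn(6),
        )
    }
    log = {"seed": config.seed, "derived_seeds": seeds, "stages": []}
    results: dict = {}

    # -- data ------------------------------------------------------------
    def load():
        if config.simulate:
            sim = config.sim or SimConfig()
            zone = sim_zone(sim, seed=seeds["sim"])
            ds, calls = zone.dataset, zone.calls
            zone.truth.to_csv(outdir / "truth.csv", index=False)
            results["zone"] = zone
        else:
            meta = gio.read_metadata(config.meta_path)
            ds = gio.read_genepop(config.genepop_path, meta=meta)
            if config.maternal_path:
                ds = gio.attach_maternal(
                    ds, gio.read_maternal_labels(config.maternal_path)
                )
            calls = (
                ac.validate_calls(pd.read_csv(config.calls_path))
                if config.calls_path
                else None
            )
        if config.exclude_loci:
            ds = ds.drop_loci(config.exclude_loci)
        return ds, calls

    dataset, calls = _stage("load", log, load)
    results["dataset"] = dataset
    gio.write_genepop(dataset, outdir / "genotypes.gen")
    dataset.meta.to_csv(outdir / "metadata.csv", index=False)

    # -- references and hybrid indices ------------------------------------
    def references():
        return gio.pool_references(
            dataset, config.ref_selector_a, config.ref_selector_b
        )

    refs = _stage("references", log, references)

    def hybrid_indices():
        est = HybridIndexEstimator(
            alpha=config.alpha_smoothing, f1_bounds=tuple(config.f1_bounds)
        )
        universe = [dataset.allele_universe(j) for j in range(dataset.n_loci)]
        est.fit(refs, allele_universe=universe)
        df = est.results_frame(dataset)
        if dataset.maternal is not None:
            df["maternal"] = dataset.maternal
        return est, df

    est, hdf = _stage("hybrid_index", log, hybrid_indices)
    results["estimator"] = est
    results["hybrid_index"] = hdf
    hdf.to_csv(outdir / "hybrid_indices.csv", index=False)

    # -- regional admixture summaries -------------------------------------
    def regions():
        return summarize_regions(hdf)

    region_summary = _stage("region_summary", log, regions)
    results["region_summary"] = region_summary
    region_summary.to_csv(outdir / "region_summary.csv", index=False)

    # -- pairwise randomization tests --------------------------------------
    def pairwise():
        focal = region_summary.loc[
            region_summary["n"] >= config.min_region_n, "region"
        ]
        out = {}
        for method, col, seed_key in (
            ("f1", "is_f1", "pairs_f1"),
            ("ci", "is_hybrid_ci", "pairs_ci"),
        ):
            flags = {
                r: hdf.loc[hdf["region"] == r, col].to_numpy(bool)
                for r in focal
            }
            if len(flags) >= 2:
                out[method] = rs.pairwise_proportion_tests(
                    flags,
                    n_reps=config.pair_reps,
                    sidedness=config.sidedness,
                    seed=seeds[seed_key],
                    alpha=config.test_alpha,
                )
            else:
                out[method] = pd.DataFrame()
        return out

    pair_tests = _stage("pairwise_tests", log, pairwise)
    results["pairwise_tests"] = pair_tests
    pair_tests["f1"].to_csv(outdir / "pairwise_f1_tests.csv", index=False)
    pair_tests["ci"].to_csv(outdir / "pairwise_ci_tests.csv", index=False)

    # -- maternal asymmetry -------------------------------------------------
    def maternal():
        if "maternal" not in hdf.columns:
            return pd.DataFrame()
        return asym.tally_maternal(hdf)

    tally = _stage("maternal_asymmetry", log, maternal)
    results["maternal"] = tally
    tally.to_csv(outdir / "maternal_tally.csv", index=False)

    # -- genetic structure ---------------------------------------------------
    def structure():
        fst = ps.pairwise_fst(dataset, min_n=config.min_n_fst)
        rst = ps.pairwise_rst(dataset, min_n=config.min_n_fst)
        coords = ps.pcoa(rst)
        return fst, rst, coords

    fst, rst, coords = _stage("structure", log, structure)
    results["fst"], results["rst"], results["pcoa"] = fst, rst, coords
    fst.to_frame().to_csv(outdir / "fst.csv")
    rst.to_frame().to_csv(outdir / "rst.csv")
    pcoa_df = coords.coordinates.copy()
    pcoa_df.to_csv(outdir / "pcoa_scores.csv")

    # -- IBD per species ------------------------------------------------------
    def ibd():
        out = {}
        hybrid_ids = set(
            hdf.loc[hdf["is_f1"] | hdf["is_hybrid_ci"], "individual"]
        )
        keep = [
            i
            for i, ind in enumerate(dataset.individual_ids)
            if ind not in hybrid_ids
        ]
        pure = dataset.subset(keep)
        for sp, seed_key in (("A", "ibd_a"), ("B", "ibd_b")):
            locs = list(
                dataset.meta.loc[dataset.meta["species"] == sp, "locality"]
            )
            sub = pure.subset(pure.indices_for_localities(locs))
            try:
                fst_sp = ps.pairwise_fst(sub, min_n=config.min_n_fst)
                geo = ps.geographic_distances(dataset.meta, fst_sp.labels)
                symp = dataset.meta.set_index("locality")["sympatry"].eq(
                    "sympatric"
                )
                out[sp] = ps.ibd_residual_randomization(
                    fst_sp,
                    geo,
                    symp,
                    n_reps=config.ibd_reps,
                    seed=seeds[seed_key],
                    mantel_perms=config.mantel_perms,
                )
            except ValueError as exc:
                logger.warning("IBD for species %s skipped: %s", sp, exc)
        return out

    ibd_results = _stage("ibd", log, ibd)
    results["ibd"] = ibd_results
    with open(outdir / "ibd.json", "w") as fh:
        json.dump(
            {
                sp: {
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "mantel_r": r.mantel_r,
                    "r_squared": r.r_squared,
                    "p_mantel": r.p_mantel,
                    "sympatry_stat": r.sympatry_stat,
                    "p_randomization": r.p_randomization,
                    "n_reps": r.n_reps,
                }
                for sp, r in ibd_results.items()
            },
            fh,
            indent=2,
        )

    # -- acoustics -------------------------------------------------------------
    def acoustic():
        if calls is None or calls.empty:
            return {}
        corrected = ac.temperature_correct(calls)
        out = {"corrected": corrected}
        fits = []
        for var in ac.CALL_VARIABLES:
            f = ac.regress_call_on_hindex(corrected, hdf, var)
            fits.append(
                dict(predictors="+".join(f.predictors), r_squared=f.r_squared,
                     p_value=f.p_value, aic=f.aic, bic=f.bic, n=f.nobs)
            )
        sel = ac.stepwise_select(corrected, hdf)
        joint = sel["fits"].get(ac.CALL_VARIABLES)
        if joint is not None:
            fits.append(
                dict(predictors="+".join(joint.predictors),
                     r_squared=joint.r_squared, p_value=joint.p_value,
                     aic=joint.aic, bic=joint.bic, n=joint.nobs)
            )
        out["fits"] = pd.DataFrame(fits)
        out["best_aic"] = "+".join(sel["best_aic"])
        out["best_bic"] = "+".join(sel["best_bic"])
        rcd_tables, rcd_fits = [], []
        for sp in ("A", "B"):
            table = ac.rcd_region_table(corrected, sp)
            if table.empty:
                continue
            rcd_tables.append(table)
            try:
                rcd_fits.append(ac.rcd_vs_admixture(table, region_summary))
            except ValueError as exc:
                logger.warning("RCD regression for species %s skipped: %s",
                               sp, exc)
        out["rcd_regions"] = (
            pd.concat(rcd_tables, ignore_index=True)
            if rcd_tables
            else pd.DataFrame()
        )
        out["rcd_vs_admixture"] = (
            pd.concat(rcd_fits, ignore_index=True) if rcd_fits else pd.DataFrame()
        )
        return out

    acoustic_out = _stage("acoustics", log, acoustic)
    results["acoustics"] = acoustic_out
    if acoustic_out:
        acoustic_out["fits"].to_csv(outdir / "acoustic_fits.csv", index=False)
        acoustic_out["rcd_regions"].to_csv(outdir / "rcd_regions.csv", index=False)
        acoustic_out["rcd_vs_admixture"].to_csv(
            outdir / "rcd_vs_admixture.csv", index=False
        )

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    results["log"] = log
    return results
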