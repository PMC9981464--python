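"""End-to-end pipeline: simulate/load -> filter/transform -> scan ->
thresholds -> peaks/BLUP -> mediation -> integration.

Each stage writes its outputs under the run directory with stable
filenames and appends retained counts, wall time and output checksums to
the manifest. All randomness flows from the root seed through a fixed
``numpy.random.SeedSequence`` spawn order (map/mosaics, covariates,
traits, mediation triplet, permutations), so a rerun with the same
config and seed reproduces every deterministic output bit-identically;
the manifest's fingerprint hashes the deterministic content (counts,
checksums, config hash) and excludes wall times.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from ._constants import N_FOUNDERS
from .config import RunConfig
from .errors import DomqtlError
from .genmap import GeneticMap, make_genetic_map
from .integrate import detect_hotspots, match_comapping
from .kinship import KinshipSet, calc_kinship
from .mediate import MediationConfig, bidirectional_scan
from .scan import find_peaks, blup_effects, permutation_thresholds, scan_genome
from .simulate import (
    GenoProbs, MediationSpec, QTLSpec, SimTraitSpec,
    mosaics_to_probs, simulate_covariates, simulate_do_mosaics,
    simulate_mediation_triplet, simulate_traits,
)
from .transform import prevalence_filter, rankz_frame

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_cohort"]


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    """Fixed per-stage integer seeds spawned from the root seed."""
    return [int(s) for s in (np.random.SeedSequence(seed).generate_state(n) % (2**31))]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def simulate_cohort(cfg: RunConfig):
    """Build the synthetic cohort described by ``cfg.simulate``.

    Returns (gmap, probs, covars, microbe traits, lipid traits, truth).
    Trait matrix layout: microbe traits are zero-inflated log-normal
    abundances, a subset carrying planted QTL; one microbe/lipid pair
    forms the mediation triplet when configured.
    """
    s = cfg.simulate
    seeds = _stage_seeds(cfg.seed)
    gmap = make_genetic_map(s.n_chr, s.markers_per_chr, s.chr_length_mbp, seed=seeds[0])
    mosaic = simulate_do_mosaics(gmap, s.n_mice, s.n_generations, seed=seeds[0] + 1)
    probs = mosaics_to_probs(mosaic, gmap, softness=s.softness)
    covars = simulate_covariates(s.n_mice, s.n_waves, seed=seeds[1])

    rng = np.random.default_rng(seeds[2])
    chroms = gmap.chromosomes
    specs = []
    for i in range(s.n_microbe_traits):
        qtls = []
        if i < s.n_qtl_traits:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = float(rng.uniform(0, gmap.lengths[chrom]))
            qtls = [QTLSpec(chrom, pos, rng.standard_normal(N_FOUNDERS), s.qtl_var_frac)]
        specs.append(
            SimTraitSpec(
                name=f"microbe_{i + 1:03d}",
                qtls=qtls,
                h2_polygenic=s.h2_polygenic,
                covar_effects={"sex": 0.2},
                noise_model="lognormal",
                zero_inflation=s.zero_inflation,
                seed=seeds[2] + 100 + i,
            )
        )
    microbe, truth_microbe = simulate_traits(probs, gmap, covars, specs)

    lipid_specs = []
    for i in range(s.n_lipid_traits - (0 if s.mediation_mode == "none" else 1)):
        lipid_specs.append(
            SimTraitSpec(
                name=f"lipid_{i + 2:03d}",
                qtls=[],
                h2_polygenic=s.h2_polygenic,
                noise_model="gaussian",
                seed=seeds[2] + 500 + i,
            )
        )
    lipid, truth_lipid = simulate_traits(probs, gmap, covars, lipid_specs)

    truth = {"microbe": truth_microbe, "lipid": truth_lipid, "mediation": None}
    if s.mediation_mode != "none":
        mspec = MediationSpec(
            chrom=s.mediation_chrom,
            pos_mbp=s.mediation_pos_mbp,
            microbe=SimTraitSpec(
                name="microbe_mediator",
                qtls=[
                    QTLSpec(
                        s.mediation_chrom, s.mediation_pos_mbp,
                        np.random.default_rng(seeds[3]).standard_normal(N_FOUNDERS),
                        s.mediation_qtl_var_frac,
                    )
                ],
                h2_polygenic=0.0,
                seed=seeds[3] + 1,
            ),
            alpha=s.mediation_alpha if s.mediation_mode == "mediated" else 0.0,
            lipid_residual_sd=s.lipid_residual_sd,
            mode=s.mediation_mode,
            seed=seeds[3] + 2,
        )
        m, l, truth_med = simulate_mediation_triplet(probs, gmap, mspec)
        microbe["microbe_mediator"] = m.to_numpy()
        lipid.insert(0, "lipid_001", l.to_numpy())
        truth["mediation"] = truth_med
    return gmap, probs, covars, microbe, lipid, truth


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    A stage failure aborts the run with the stage name and persists the
    partial manifest.
    """
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "stages": {},
        "counts": {},
        "checksums": {},
        "notices": [],
    }
    cfg.to_yaml(out / "config.resolved.yaml")
    logger.info("run start: seed=%s config_hash=%s", cfg.seed, cfg.hash())
    current_stage = "setup"

    def _record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {"wall_s": round(time.perf_counter() - t0, 3)}
        manifest["counts"].update(counts)
        logger.info("stage %s done in %.2fs %s", stage, time.perf_counter() - t0, counts)

    try:
        # ------------------------------------------------ simulate / load
        current_stage = "simulate"
        t0 = time.perf_counter()
        if cfg.simulate is not None:
            gmap, probs, covars, microbe, lipid, truth = simulate_cohort(cfg)
            dio.write_probs(probs, out / "probs.h5")
            dio.write_traits(covars, out / "covariates.tsv")
            dio.write_traits(microbe, out / "microbe_traits.tsv")
            dio.write_traits(lipid, out / "lipid_traits.tsv")
            dio.write_json(truth, out / "truth.json")
        else:
            inp = cfg.inputs
            probs = dio.read_probs(inp.probs)
            covars = dio.read_traits(inp.covariates)
            microbe = dio.read_traits(inp.microbe_traits, kind="microbe")
            lipid = dio.read_traits(inp.lipid_traits, kind="lipid")
            truth = None
        _record("simulate", t0,
                n_mice=probs.n_individuals, n_markers=probs.n_markers,
                n_microbe_traits=microbe.shape[1], n_lipid_traits=lipid.shape[1])

        # ------------------------------------------------ prevalence filter
        current_stage = "prevalence_filter"
        t0 = time.perf_counter()
        if cfg.prevalence.enabled:
            microbe, rep = prevalence_filter(
                microbe, cfg.prevalence.min_value, cfg.prevalence.min_fraction
            )
            _record("prevalence_filter", t0,
                    microbe_traits_kept=rep.n_kept, microbe_traits_dropped=rep.n_dropped)
        else:
            manifest["notices"].append("prevalence filter disabled")
            _record("prevalence_filter", t0, microbe_traits_kept=microbe.shape[1])

        # ------------------------------------------------ transform
        current_stage = "transform"
        t0 = time.perf_counter()
        if cfg.analysis.transform == "rankz":
            microbe_t = rankz_frame(microbe)
            lipid_t = rankz_frame(lipid)
        else:
            microbe_t, lipid_t = microbe, lipid
        _record("transform", t0,
                microbe_traits_transformed=microbe_t.shape[1],
                lipid_traits_transformed=lipid_t.shape[1])

        # ------------------------------------------------ kinship
        current_stage = "kinship"
        t0 = time.perf_counter()
        kin = None
        if cfg.analysis.kinship != "none":
            mode = "loco" if cfg.analysis.kinship == "loco" and len(probs.chromosomes) > 1 else "overall"
            kin = calc_kinship(probs, mode=mode)
        _record("kinship", t0)

        # ------------------------------------------------ scans
        current_stage = "scan"
        t0 = time.perf_counter()
        cache: dict = {}
        scans = {}
        frames = []
        for df in (microbe_t, lipid_t):
            for trait in df.columns:
                res = scan_genome(df[trait], covars, probs, kin,
                                  kinship_mode=cfg.analysis.kinship, trait=trait, cache=cache)
                scans[trait] = res
                tab = res.table.copy()
                tab.insert(0, "trait", trait)
                frames.append(tab)
        scan_long = pd.concat(frames, ignore_index=True)
        scan_long.to_csv(out / "scans.tsv", sep="\t", index=False)
        _record("scan", t0, n_scans=len(scans))

        # ------------------------------------------------ permutation thresholds
        current_stage = "thresholds"
        t0 = time.perf_counter()
        seeds = _stage_seeds(cfg.seed)
        threshold = cfg.analysis.suggestive_lod
        if cfg.analysis.n_perm > 0:
            traits_for_thr = (
                list(scans) if cfg.analysis.threshold_traits == "all" else [next(iter(scans))]
            )
            thr_by_trait = {}
            for trait in traits_for_thr:
                src = microbe_t if trait in microbe_t.columns else lipid_t
                thr = permutation_thresholds(
                    src[trait], covars, probs, kin,
                    n_perm=cfg.analysis.n_perm, alphas=cfg.analysis.alphas,
                    seed=seeds[5], kinship_mode=cfg.analysis.kinship,
                    refit_h2=cfg.analysis.refit_h2_in_perm, cache=cache,
                )
                thr_by_trait[trait] = thr
            dio.write_json(
                {t: {str(a): v for a, v in th.thresholds.items()} for t, th in thr_by_trait.items()},
                out / "thresholds.json",
            )
            threshold = float(np.mean([th.thresholds[cfg.analysis.alphas[0]]
                                       for th in thr_by_trait.values()]))
            _record("thresholds", t0, n_perm=cfg.analysis.n_perm,
                    threshold_alpha05=round(threshold, 3))
        else:
            manifest["notices"].append("thresholds stage skipped (n_perm=0); peaks use suggestive LOD")
            _record("thresholds", t0)

        # ------------------------------------------------ peaks + BLUP
        current_stage = "peaks"
        t0 = time.perf_counter()
        all_peaks = []
        for trait, res in scans.items():
            all_peaks.extend(find_peaks(res, threshold=min(threshold, cfg.analysis.suggestive_lod)))
        dio.write_peaks(all_peaks, out / "peaks.tsv")
        effects = {}
        for p in all_peaks:
            src = microbe_t if p.trait in microbe_t.columns else lipid_t
            e = blup_effects(src[p.trait], covars, probs, p.chrom, p.marker_idx, kin,
                             kinship_mode=cfg.analysis.kinship,
                             locus={"chrom": p.chrom, "pos_mbp": p.pos_mbp, "trait": p.trait})
            effects[f"{p.trait}@{p.chrom}:{p.pos_mbp:.3f}"] = e
        dio.write_effects(effects, out / "allele_effects.json")
        _record("peaks", t0, n_peaks=len(all_peaks))

        # ------------------------------------------------ mediation
        current_stage = "mediation"
        t0 = time.perf_counter()
        med_cfg = MediationConfig(
            z_threshold=cfg.mediation.z_threshold,
            min_overlap=cfg.mediation.min_overlap,
            suggestive_lod=cfg.analysis.suggestive_lod,
            min_group_size=cfg.mediation.min_group_size,
            robust=cfg.mediation.robust,
        )
        lipid_peaks = [p for p in all_peaks if p.trait in lipid_t.columns]
        microbe_peaks = [p for p in all_peaks if p.trait in microbe_t.columns]
        direction = cfg.mediation.direction
        result = bidirectional_scan(
            lipid_t, microbe_t, lipid_peaks, microbe_peaks,
            covars, probs, kin, cfg.analysis.kinship, med_cfg,
            window_mbp=cfg.integration.window_mbp,
        )
        wanted = {"a2b": ("a_to_b",), "b2a": ("b_to_a",), "both": ("a_to_b", "b_to_a")}[direction]
        med_rows = []
        n_flagged = 0
        for direction_key in wanted:
            for ms in result[direction_key]:
                rec = ms.records.copy()
                rec.insert(0, "outcome", ms.outcome)
                rec.insert(1, "chrom", ms.locus["chrom"])
                rec.insert(2, "pos_mbp", ms.locus["pos_mbp"])
                rec.insert(3, "direction", direction_key)
                med_rows.append(rec)
                n_flagged += int(rec["flagged"].sum())
        med_table = (
            pd.concat(med_rows, ignore_index=True)
            if med_rows
            else pd.DataFrame(columns=["outcome", "chrom", "pos_mbp", "direction",
                                       "candidate", "n", "lod_orig", "lod_adj",
                                       "drop", "z", "flagged"])
        )
        med_table.to_csv(out / "mediation.tsv", sep="\t", index=False)
        if not med_rows:
            manifest["notices"].append(result["notice"])
        _record("mediation", t0, n_mediation_records=len(med_table),
                n_flagged_mediators=n_flagged)

        # ------------------------------------------------ integration
        current_stage = "integration"
        t0 = time.perf_counter()
        pairs = match_comapping(microbe_peaks, lipid_peaks, cfg.integration.window_mbp)
        pd.DataFrame([vars(p) for p in pairs]).to_csv(out / "comap_pairs.tsv", sep="\t", index=False)
        hotspots = detect_hotspots(
            all_peaks, bin_mbp=cfg.integration.bin_mbp,
            min_traits=cfg.integration.min_hotspot_traits,
            lod_floor=cfg.integration.hotspot_lod_floor,
        )
        pd.DataFrame(
            [
                {"chrom": h.chrom, "lo_mbp": h.lo_mbp, "hi_mbp": h.hi_mbp,
                 "n_traits": h.n_traits, "traits": ";".join(h.traits)}
                for h in hotspots
            ],
            columns=["chrom", "lo_mbp", "hi_mbp", "n_traits", "traits"],
        ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
        _record("integration", t0, n_comap_pairs=len(pairs), n_hotspots=len(hotspots))

        # ------------------------------------------------ manifest
        for f in sorted(out.iterdir()):
            if f.suffix in (".tsv", ".json", ".yaml", ".h5") and f.name != "manifest.json":
                manifest["checksums"][f.name] = _sha256(f)
        fingerprint_src = {
            "seed": manifest["seed"],
            "config_hash": manifest["config_hash"],
            "counts": manifest["counts"],
            "checksums": {k: v for k, v in manifest["checksums"].items() if k != "run.log"},
        }
        manifest["fingerprint"] = hashlib.sha256(
            repr(sorted(fingerprint_src.items())).encode()
        ).hexdigest()[:16]
        dio.write_json(manifest, out / "manifest.json")
        logger.info("run complete: fingerprint=%s", manifest["fingerprint"])
        return manifest
    except Exception as e:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(e)
        dio.write_json(manifest, out / "manifest.json")
        logger.error("stage %s failed: %s", current_stage, e)
        raise DomqtlError(f"pipeline stage {current_stage!r} failed: {e}") from e
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
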