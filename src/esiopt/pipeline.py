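"""End-to-end experiment driver: forward model -> ROI -> simulated epochs ->
noise grid -> channel optimization scenarios -> motor-imagery classification.

Artifacts land in an output directory, every table as CSV and every array as
an ``.npz`` container with JSON sidecar, all stamped with the configuration
hash and master seed (``manifest.json``).  Reruns with the same configuration
are byte-identical for all CSV/JSON outputs.

Seed scheme: each stage draws from ``SeedSequence(master_seed, spawn_key)``
with a fixed per-stage key (forward lattice = 0, simulation = 1, noise = 2,
optimization = 3, classification = 4); no global RNG state is used anywhere.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import classify as cls
from . import io as eio
from . import optimize as opt
from . import simulate as sim
from .config import RunConfig
from .headmodel import TEN10_LABELS, ShellModel, build_montage, build_source_space, forward_gain
from .inverse import lambda2_for_snr

logger = logging.getLogger("esiopt")

_STAGE_KEYS = {"forward": 0, "simulate": 1, "noise": 2, "optimize": 3, "classify": 4}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the master seed."""
    ss = np.random.SeedSequence(master, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _scenario_spec(name: str, montage) -> opt.ConstraintSpec:
    if name == "none":
        return opt.ConstraintSpec()
    if name == "ten10":
        return opt.ConstraintSpec(allowed_labels=frozenset(TEN10_LABELS))
    if name == "symmetric":
        return opt.ConstraintSpec(symmetric=True)
    if name == "ten10_symmetric":
        return opt.ConstraintSpec(allowed_labels=frozenset(TEN10_LABELS), symmetric=True)
    raise ValueError(f"unknown optimization scenario {name!r}")


def build_forward(config: RunConfig):
    hc = config.headmodel
    montage = build_montage(hc.montage_system, hc.scalp_radius)
    src = build_source_space(
        hc.n_per_hemisphere, hc.cortex_radius, stage_seed(config.seed, "forward"), hc.z_min
    )
    shell = ShellModel(hc.radii, hc.conductivities, hc.series_terms)
    return forward_gain(shell, montage, src)


def run_experiment(config: RunConfig, outdir) -> dict:
    """Run every stage; partial failures are logged and reported.

    Returns a result bundle ``{stage: 'ok' | 'failed: ...'}`` plus the key
    artifacts in memory; writes all declared outputs under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    bundle: dict = {"status": status}
    timings: dict[str, float] = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
            status[name] = "ok"
            return result
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.exception("stage %s failed", name)
            status[name] = f"failed: {exc}"
            return None
        finally:
            timings[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: %s (%.1fs)", name, status[name], timings[name])

    def forward():
        lf = build_forward(config)
        eio.write_montage_sfp(lf.montage, outdir / "montage.sfp")
        eio.save_leadfield(lf, outdir / "leadfield.npz", {"seed": config.seed})
        return lf

    lf = stage("forward", forward)
    if lf is None:
        _write_manifest(config, status, timings, outdir)
        return bundle
    bundle["leadfield"] = lf

    def roi():
        rc = config.roi
        markers = (
            np.asarray(rc.markers, float)
            if rc.markers is not None
            else sim.default_hand_knob_markers(config.headmodel.cortex_radius)
        )
        indices = sim.select_roi(lf.source_space, sim.RoiSpec(markers, rc.k))
        np.savetxt(outdir / "roi_indices.csv", indices[None], fmt="%d", delimiter=",")
        return indices

    roi_indices = stage("roi", roi)
    if roi_indices is None:
        _write_manifest(config, status, timings, outdir)
        return bundle
    bundle["roi_indices"] = roi_indices

    def simulate():
        sc = config.simulation
        cfg = sim.SimConfig(
            duration=sc.duration,
            sfreq=sc.sfreq,
            epochs_per_source=sc.epochs_per_source,
            background_ratio=sc.background_ratio,
            background_min_dist=sc.background_min_dist,
        )
        clean, _ = sim.simulate_epochs(
            lf, roi_indices, cfg, stage_seed(config.seed, "simulate")
        )
        eio.save_epochs(clean, outdir / "epochs_clean.npz")
        noisy = {}
        for snr in sc.snr_grid:
            es = sim.add_noise(clean, snr, stage_seed(config.seed, "noise") + int(round(snr)))
            eio.save_epochs(es, outdir / f"epochs_snr{snr:g}dB.npz")
            eio.epochs_metadata_frame(es).to_csv(
                outdir / f"epochs_snr{snr:g}dB_trials.csv", index=False
            )
            noisy[snr] = es
        return clean, noisy

    simulated = stage("simulate", simulate)
    if simulated is None:
        _write_manifest(config, status, timings, outdir)
        return bundle
    clean, noisy = simulated
    bundle["epochs"] = {"clean": clean, **noisy}

    def optimize():
        oc = config.optimization
        dataset = noisy.get(oc.snr_db, clean)
        lam = lambda2_for_snr(lf, dataset.snr_db)
        results = {}
        for name in oc.scenarios:
            spec = _scenario_spec(name, lf.montage)
            cfg = opt.GaConfig(
                population_size=oc.population_size,
                n_generations=oc.n_generations,
                crossover_rate=oc.crossover_rate,
                mutation_rate=oc.mutation_rate,
                seed=stage_seed(config.seed, "optimize"),
                esi_method=oc.esi_method,
                lambda2=lam,
            )
            res = opt.run_nsga2(lf, dataset, spec=spec, cfg=cfg)
            eio.write_archive_csv(res, lf.montage, outdir / f"archive_{name}.csv")
            eio.write_pareto_csv(res, lf.montage, outdir / f"pareto_{name}.csv")
            eio.write_best_per_count_json(res, lf.montage, outdir / f"best_{name}.json")
            results[name] = res
        return results

    ga_results = stage("optimize", optimize)
    if ga_results is not None:
        bundle["optimization"] = ga_results

    def classify():
        cc = config.classification
        left = roi_indices[lf.source_space.hemisphere[roi_indices] == "L"]
        right = roi_indices[lf.source_space.hemisphere[roi_indices] == "R"]
        mi = sim.simulate_mi_dataset(
            lf,
            left,
            right,
            sim.MiConfig(n_trials_per_class=cc.n_trials_per_class, erd_depth=cc.erd_depth),
            stage_seed(config.seed, "classify"),
        )
        prepared = cls.preprocess(mi, cls.PreprocConfig())
        lam = lambda2_for_snr(lf, sim.MiConfig().sensor_snr_db)
        report: dict = {}
        for space in cc.spaces:
            spec = cls.FeatureSpec(
                space,
                cc.n_csp_components,
                roi_indices if space == "source" else None,
                lam,
            )
            for tag in cc.classifiers:
                cv = cls.cross_validate(
                    prepared,
                    feature_spec=spec,
                    classifier=tag,
                    n_repeats=cc.n_repeats,
                    test_frac=cc.test_frac,
                    seed=stage_seed(config.seed, "classify"),
                    lf=lf,
                )
                report[f"{space}/{tag}"] = cv.to_dict()
        (outdir / "classification_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True)
        )
        return report

    report = stage("classify", classify)
    if report is not None:
        bundle["classification"] = report

    _write_manifest(config, status, timings, outdir)
    return bundle


def _write_manifest(config: RunConfig, status, timings, outdir: Path) -> None:
    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "status": status,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "timings.log").write_text(
        "\n".join(f"{k}\t{v}" for k, v in timings.items()) + "\n"
    )
    config.to_json(outdir / "config.json")
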