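"""Pipeline orchestration: simulate or read recordings, run trace analysis
and statistics, and persist every intermediate as CSV/TIFF plus a log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, stats, synthetic, traces
from .config import PipelineConfig
from .datatypes import StimWindow

log = logging.getLogger("nmjcal")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return a bundle of output paths.

    Stages: simulate (or read) -> per-trace analysis (bleach correction,
    smoothing, ΔF/F, evoked features) -> per-larva datapoints ->
    genotype x frequency statistics. Every intermediate is persisted under
    ``config.output_dir`` and the log records parameters and seed.
    """
    config = config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("pipeline start; config=%s", json.dumps(config.__dict__, default=str))

    try:
        if config.simulate:
            stage = "simulate"
            trs, truths, records = synthetic.simulate_cohort(
                n_larvae_per_genotype=config.n_larvae_per_genotype,
                frequencies_hz=config.frequencies_hz,
                compartment=config.compartment,
                genotype_scales={"WT": 1.0, "mutant": config.mutant_scale},
                noise_sd_fraction=config.noise_sd_fraction,
                seed=config.seed, duration_s=config.duration_s,
                stim_onset_s=config.stim_onset_s,
                stim_duration_s=config.stim_duration_s)
        else:
            stage = "read"
            trs, records = [], []
            for path in sorted(Path(config.input_dir).glob("*.csv")):
                tr = io.read_trace(path)
                trs.append(tr)
                records.append({"larva_id": tr.meta.get("larva_id", path.stem),
                                "genotype": tr.meta.get("genotype", "other"),
                                "frequency_hz": float(
                                    tr.stim.frequency_hz if tr.stim else 0.0)})
            if not trs:
                raise FileNotFoundError(
                    f"no trace CSVs found under {config.input_dir!r}")

        stage = "trace_analysis"
        rows = []
        for tr, rec in zip(trs, records):
            feats, dff_tr, model = traces.analyze_trace(
                tr, smoothing_window=config.smoothing_window_frames,
                noise_band_k=config.noise_band_k)
            rows.append({**rec, "resting_F": feats.resting_F,
                         "max_F": feats.max_F, "delta_F": feats.delta_F,
                         "max_dff": feats.max_dff,
                         "min_dff_post_stim": feats.min_dff_post_stim,
                         "time_to_peak_s": feats.time_to_peak_s,
                         "t50_recovery_s": feats.t50_recovery_s,
                         "t100_recovery_s": feats.t100_recovery_s,
                         "bleach_a": model.a, "bleach_b": model.b})
        features = pd.DataFrame(rows)
        features_path = out / "features.csv"
        features.to_csv(features_path, index=False)
        log.info("wrote %s (%d traces)", features_path, len(features))

        stage = "stats"
        datapoints = stats.larval_datapoints(
            features, value="max_dff", keep=("genotype", "frequency_hz"))
        datapoints_path = out / "larval_datapoints.csv"
        datapoints.to_csv(datapoints_path, index=False)

        result = stats.multi_group_test(datapoints, value="max_dff")
        norm = traces.normalize_group_to_control(
            datapoints["max_dff"], datapoints["genotype"],
            control_label=config.control_label)
        datapoints = datapoints.assign(max_dff_norm=norm)

        report_path = out / "stats_report.txt"
        with open(report_path, "w") as fh:
            fh.write("Genotype x frequency mixed-effects repeated-measures ANOVA\n")
            for term in ("between_effect", "within_effect", "interaction"):
                eff = result.extra[term]
                fh.write(f"  {term}: chi2={eff['chi2']:.3f} "
                         f"df={eff['df']} p={eff['p']:.4g}\n")
            for g in result.groups:
                fh.write(f"  {g.label}: n={g.n} mean={g.mean:.4f} sem={g.sem:.4f}\n")
            mutant_norm = datapoints.loc[
                datapoints["genotype"] != config.control_label, "max_dff_norm"]
            fh.write(f"  normalized non-control mean: {mutant_norm.mean():.4f}\n")
        log.info("stats written to %s", report_path)
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    return {"features": features_path, "datapoints": datapoints_path,
            "report": report_path, "log": out / "pipeline.log",
            "genotype_p": result.extra["between_effect"]["p"]}


def make_fixtures(seed: int = 0, outdir: str = "fixtures") -> dict:
    """Write a small bundled test dataset with ground-truth sidecars.

    Contents: a drifting two-bouton movie (TIFF + label masks), a static
    marker/reference image pair, and a WT + mutant pair of evoked traces
    (CSV), each with its SimTruth alongside as JSON.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)

    movie_cfg = synthetic.SimConfig(
        compartment="cytosol", duration_s=2.0, frame_rate_hz=10.0,
        stim=StimWindow(0.5, 0.5, 40.0),
        geometry=synthetic.Geometry(n_boutons=2, bouton_radius_px=4,
                                    image_shape=(48, 48),
                                    drift_px_per_frame=(0.25, 0.0)),
        seed=rng_seed)
    movie, rois, truth = synthetic.simulate_movie(movie_cfg)
    io.write_movie(out / "movie.tif", movie)
    io.write_label_mask(out / "movie_rois.tif", rois, movie.frame_shape)
    io.write_truth(out / "movie_truth.json",
                   {"shifts_px": truth.shifts_px,
                    "bouton_centers_px": truth.bouton_centers_px})

    static_cfg = synthetic.SimConfig(
        compartment="er",
        geometry=synthetic.Geometry(n_boutons=3, bouton_radius_px=6,
                                    image_shape=(96, 96)),
        seed=rng_seed + 1)
    marker, reference, nmj_roi, struth = synthetic.simulate_static_pair(static_cfg)
    import tifffile
    tifffile.imwrite(str(out / "static_pair.tif"),
                     np.stack([marker, reference]).astype(np.float32))
    io.write_label_mask(out / "static_nmj.tif", [nmj_roi], marker.shape)
    io.write_truth(out / "static_truth.json",
                   {"puncta_pixels": np.argwhere(struth.puncta_mask)})

    for genotype, scale in (("WT", 1.0), ("mutant", 0.5)):
        cfg = synthetic.SimConfig(
            compartment="cytosol", genotype_scale=scale,
            noise=synthetic.NoiseParams(gaussian_sd=10.0),
            seed=rng_seed + (2 if genotype == "WT" else 3))
        tr, t_truth = synthetic.simulate_trace(cfg)
        tr.meta.update(genotype=genotype, larva_id=f"{genotype}_0")
        io.write_trace(out / f"trace_{genotype}.csv", tr)
        io.write_truth(out / f"trace_{genotype}_truth.json",
                       {"true_peak_dff": t_truth.true_peak_dff,
                        "bleach_a": t_truth.bleach_a,
                        "bleach_b": t_truth.bleach_b})
    return {"dir": out}
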