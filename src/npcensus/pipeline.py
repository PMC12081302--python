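"""Pipeline orchestration and report artifacts.

``run_pipeline`` chains the stages — simulate, whole-pore census by template
matching, per-ring completeness, diameter measurement and over-stretch
classification, optional symmetry classification — into a run directory of
CSV tables and a log, fully reproducible from (config, seed).  The report
helpers render the peak max-projection plots and pseudo-composite maps used
to present template-matching results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .census import (RingCensus, census_from_peaks, classify_opening,
                     completeness_histogram, fit_ring_circle, opposing_pair_diameter)
from .config import PipelineConfig
from .errors import NPCensusError
from .matching import Peak, TemplateMatcher, ThreeRingConfig, peaks_to_table, run_three_ring_tm
from .synthetic import (RING_IDS, DesignGroup, build_protomer_template, simulate_dataset)
from .volumes import (Pose, Volume, WedgeSpec, make_inplane_grid, make_rotation_grid,
                      transform)

__all__ = ["run_pipeline", "render_peak_plot", "render_pseudo_composite", "census_dataset"]


def _setup_logger(run_dir: Path) -> logging.Logger:
    logger = logging.getLogger(f"npcensus.run.{run_dir.name}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(run_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    sh = logging.StreamHandler()
    sh.setLevel(logging.WARNING)
    logger.addHandler(sh)
    return logger


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def build_matchers(config: PipelineConfig, box_voxels: int | None = None
                   ) -> dict[str, TemplateMatcher]:
    """Rotated-template matcher cache for the three ring templates."""
    box = box_voxels or config.box_voxels
    grid = (make_inplane_grid(config.angular_increment_deg) if config.inplane_only
            else make_rotation_grid(config.angular_increment_deg))
    from .synthetic import analytic_protomer_rotator

    matchers = {}
    for ring in RING_IDS:
        tpl, mask = build_protomer_template(ring, config.voxel_size_nm)
        matchers[ring] = TemplateMatcher(
            tpl, mask, grid, (box,) * 3,
            rotator=analytic_protomer_rotator(ring, config.voxel_size_nm))
    return matchers


def census_dataset(results, config: PipelineConfig,
                   matchers: Mapping[str, TemplateMatcher] | None = None,
                   logger: logging.Logger | None = None):
    """Per-pore three-ring TM census and diameter measurement.

    Returns (census list, peaks tables list, diameter table rows).
    """
    from .matching import build_membrane_decoy

    if matchers is None:
        matchers = build_matchers(config)
    box = next(iter(matchers.values())).vol_shape
    decoy = build_membrane_decoy(config.voxel_size_nm, box)
    tm_cfg = ThreeRingConfig(
        k_sd=config.k_sd,
        angular_increment_deg=config.angular_increment_deg,
        inplane_only=config.inplane_only,
        min_sep_voxels=config.nms_radius_voxels,
        tol_axis_deg=config.tol_axis_deg,
        tol_tangent_deg=config.tol_tangent_deg,
    )
    censuses: list[RingCensus] = []
    peak_tables = []
    diam_rows = []
    for i, res in enumerate(results):
        peaks = run_three_ring_tm(res.volume, {}, {}, tm_cfg, matchers=matchers,
                                  decoy_matcher=decoy)
        census = census_from_peaks(peaks, res.phantom.symmetry_n,
                                   voxel_size_nm=config.voxel_size_nm)
        censuses.append(census)
        tab = peaks_to_table(peaks)
        tab.insert(0, "pore_id", i)
        peak_tables.append(tab)
        row = {"pore_id": i, "discarded": census.discarded,
               "true_diameter_nm": res.phantom.diameter_nm,
               "true_class": classify_opening(res.phantom.diameter_nm)}
        ir_peaks = peaks.get("IR", [])
        if len(ir_peaks) >= 3:
            pos = np.stack([p.position for p in ir_peaks])
            try:
                _, radius_nm, resid = fit_ring_circle(pos, config.voxel_size_nm)
                row["circle_fit_nm"] = 2.0 * radius_nm
                row["circle_fit_class"] = classify_opening(2.0 * radius_nm)
                row["circle_rms_nm"] = resid
            except NPCensusError:
                pass
            if len(ir_peaks) == res.phantom.symmetry_n and res.phantom.symmetry_n % 2 == 0:
                rec = opposing_pair_diameter(pos, res.phantom.symmetry_n,
                                             config.voxel_size_nm)
                row["opposing_pairs_nm"] = rec.diameter_nm
        diam_rows.append(row)
        if logger and census.discarded:
            logger.info("pore %d discarded: %s", i, census.reason)
    return censuses, peak_tables, diam_rows


def run_pipeline(config: PipelineConfig, design: Sequence[DesignGroup],
                 out_dir: str | Path, run_symmetry: bool = False) -> Path:
    """Execute simulate -> TM census -> geometry (-> symmetry) end to end.

    Writes manifest.csv, peaks.csv, census.csv, diameters.csv,
    completeness_*.csv, summary.csv, config.yaml and run.log into
    ``out_dir``; identical (config, design, seed) reproduce identical CSVs.
    """
    t0 = time.time()
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logger = _setup_logger(run_dir)
    logger.info("npcensus %s, config %s", __version__, _config_hash(config))
    config.to_yaml(run_dir / "config.yaml")

    stage = "simulate"
    try:
        wedge = WedgeSpec(config.tilt_min_deg, config.tilt_max_deg)
        results, manifest = simulate_dataset(
            design, box_voxels=config.box_voxels, voxel_size_nm=config.voxel_size_nm,
            snr=config.snr, wedge=wedge, seed=config.seed)
        manifest.to_csv(run_dir / "manifest.csv", index=False)
        logger.info("simulated %d pores", len(results))

        stage = "census"
        censuses, peak_tables, diam_rows = census_dataset(results, config, logger=logger)
        pd.concat(peak_tables, ignore_index=True).to_csv(run_dir / "peaks.csv", index=False)
        census_rows = []
        for i, c in enumerate(censuses):
            census_rows.append({
                "pore_id": i, "symmetry_n": c.symmetry_n,
                "cr_count": c.counts["CR"], "ir_count": c.counts["IR"],
                "nr_count": c.counts["NR"],
                "cr_gap_deg": c.largest_gap_deg["CR"], "nr_gap_deg": c.largest_gap_deg["NR"],
                "discarded": c.discarded, "reason": c.reason})
        pd.DataFrame(census_rows).to_csv(run_dir / "census.csv", index=False)
        for n in sorted({c.symmetry_n for c in censuses}):
            sub = [c for c in censuses if c.symmetry_n == n]
            completeness_histogram(sub).to_csv(run_dir / f"completeness_n{n}.csv")

        stage = "geometry"
        diam = pd.DataFrame(diam_rows)
        diam.to_csv(run_dir / "diameters.csv", index=False)

        summary_rows = []
        for i, (c, row) in enumerate(zip(censuses, diam_rows)):
            summary_rows.append({
                "pore_id": i,
                "symmetry_n": c.symmetry_n,
                "cr_count": c.counts["CR"], "ir_count": c.counts["IR"],
                "nr_count": c.counts["NR"], "discarded": c.discarded,
                "diameter_nm": row.get("circle_fit_nm", np.nan),
                "stretch_class": row.get("circle_fit_class", ""),
            })
        pd.DataFrame(summary_rows).to_csv(run_dir / "summary.csv", index=False)

        if run_symmetry:
            stage = "symmetry"
            from .averaging import ParticleSet
            from .symmetry import build_class_references, classify_by_reference
            from .volumes import Rotation

            # references from ground-truth-aligned particles: the synthetic
            # stand-in for whole-pore alignment plus the manual pre-sort
            labels = manifest["symmetry_n"].to_numpy()
            align = [Pose(shift=-np.array([r.shift_x, r.shift_y, r.shift_z]),
                          rotation=Rotation.about_z(-r.phase_deg))
                     for r in manifest.itertuples()]
            ps = ParticleSet([r.volume for r in results], align)
            refs = build_class_references(ps, labels,
                                          sorted(set(int(v) for v in labels)))
            req = ("all" if config.classification_consistency == "all"
                   else int(config.classification_consistency))
            calls = []
            for i, res in enumerate(results):
                call = classify_by_reference(
                    res.volume, refs, repeats=config.classification_repeats,
                    required_consistency=req, seed=config.seed + i)
                calls.append({"pore_id": i, "label": call.label,
                              "votes": ",".join(map(str, call.votes)),
                              "method": call.method, "reason": call.reason})
            pd.DataFrame(calls).to_csv(run_dir / "symmetry.csv", index=False)
    except NPCensusError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise NPCensusError(f"pipeline stage '{stage}' failed: {exc}") from exc

    logger.info("pipeline complete in %.1f s", time.time() - t0)
    return run_dir


# ---------------------------------------------------------------------------
# report artifacts
# ---------------------------------------------------------------------------


def render_peak_plot(volume: Volume, peaks: Sequence[Peak], half_depth: int = 15,
                     path: str | Path | None = None) -> np.ndarray:
    """Max-projection peak plot: the maximum over the 31-slice axial band
    (±``half_depth``) around the peaks' z positions, clipped at the volume
    edges; peak (x, y) positions are annotated when saving."""
    data = volume.data
    nz = data.shape[0]
    if len(peaks) == 0:
        proj = data.max(axis=0)
    else:
        sel = np.zeros(nz, dtype=bool)
        for p in peaks:
            z = int(round(p.position[2]))
            sel[max(z - half_depth, 0):min(z + half_depth + 1, nz)] = True
        proj = data[sel].max(axis=0)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(proj, origin="lower", cmap="gray")
        for p in peaks:
            ax.plot(p.position[0], p.position[1], "r+", markersize=8)
        ax.set_xlabel("x (voxels)")
        ax.set_ylabel("y (voxels)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return proj


def render_pseudo_composite(peaks: Sequence[Peak], templates: Mapping[str, Volume],
                            box_voxels: int, voxel_size_nm: float) -> Volume:
    """Back-plot templates at every peak pose into one additive composite map.

    Ring templates with known analytic blob models are painted exactly;
    arbitrary templates are resampled trilinearly.
    """
    from .synthetic import _BLOBS, _paint_protomer, _paste_rotated

    out = np.zeros((box_voxels,) * 3, dtype=np.float32)
    for p in peaks:
        ring = p.ring_id or "IR"
        if ring in _BLOBS:
            _paint_protomer(out, ring, p.rotation, p.position, voxel_size_nm)
        else:
            _paste_rotated(out, templates[ring], p.rotation, p.position)
    return Volume(out, voxel_size_nm)
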