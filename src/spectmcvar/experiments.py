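"""Experiment drivers: noise realizations, count thinning, and the two
study designs (bias on the cylinder phantom, paired variance on the
NEMA-like phantom), reproducing the comparison of conventional-TEW and
hybrid-MC reconstruction at desk scale on synthetic data.

Every random stream is a deterministic function of the master seed and a
named purpose, so a config plus seed reproduces every table bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grids import ActivityImage, Grid3D
from .metrics import (CountSeries, compare_variability, recovery_coefficient,
                      roi_counts)
from .phantoms import build_cylinder_sphere_phantom, build_nema_like_phantom, default_grid
from .projections import ProjectionSet, lu177_tew_windows
from .projector import PSFModel, default_geometry
from .recon import ReconConfig, reconstruct_conventional, reconstruct_hybrid_mc
from .transport import TransportConfig, mix_seed, simulate_acquisition


@dataclass
class ExperimentConfig:
    """Desk-scale defaults; ``full`` doubles the matrix and angle count."""

    master_seed: int = 0
    grid_shape: tuple = (64, 64, 48)
    voxel_mm: float = 4.8
    n_angles: int = 48
    orbit_radius_mm: float = 150.0
    time_per_projection_s: float = 15.0
    n_histories_data: int = 10_000_000
    n_histories_forward: int = 2_000_000
    n_iterations: int = 10
    n_subsets: int = 8
    n_realizations: int = 50
    target_total_peak_counts: float = 150_000.0
    thinning_fraction: float = 4.0 / 25.0
    n_subsamples: int = 6
    psf: PSFModel = field(default_factory=PSFModel)

    def grid(self) -> Grid3D:
        return Grid3D(self.grid_shape, (self.voxel_mm,) * 3)

    def geometry(self, grid):
        return default_geometry(grid, self.n_angles, self.orbit_radius_mm,
                                self.time_per_projection_s)

    def provenance(self) -> dict:
        d = asdict(self)
        d["psf"] = {"sigma0": self.psf.sigma0, "slope": self.psf.slope}
        return d


def full_scale(cfg: ExperimentConfig) -> ExperimentConfig:
    """Clinical-protocol matrix: 128x128, 96 angles."""
    out = ExperimentConfig(**{**asdict(cfg), "psf": cfg.psf})
    out.grid_shape = (128, 128, 96)
    out.n_angles = 96
    return out


def poisson_realizations(proj: ProjectionSet, n: int, seed: int) -> list[ProjectionSet]:
    """n independent Poisson samples of an expected-count projection set."""
    if proj.noise_state != "expected":
        raise ValueError("input must be an expected-count ProjectionSet")
    out = []
    for i in range(n):
        rng = np.random.default_rng(mix_seed(seed, 101, i))
        counts = rng.poisson(proj.counts).astype(np.float64)
        out.append(ProjectionSet(
            counts=counts, geom=proj.geom, windows=list(proj.windows),
            noise_state="poisson_sampled",
            meta={**proj.meta, "realization": i, "noise_seed": seed}))
    return out


def thin_counts(proj: ProjectionSet, fraction: float, n_sets: int,
                seed: int) -> list[ProjectionSet]:
    """Binomial count thinning: emulates shorter acquisitions.

    Each output pixel is Binomial(count, fraction); expected totals are
    ``fraction`` times the input totals and the ROI-count variability
    scales as 1/sqrt(fraction).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if proj.noise_state != "poisson_sampled":
        raise ValueError("thinning applies to sampled (integer-count) data")
    counts = proj.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("thinning requires integer counts")
    ints = np.round(counts).astype(np.int64)
    out = []
    for i in range(n_sets):
        rng = np.random.default_rng(mix_seed(seed, 202, i))
        thinned = rng.binomial(ints, fraction).astype(np.float64)
        out.append(ProjectionSet(
            counts=thinned, geom=proj.geom, windows=list(proj.windows),
            noise_state="poisson_sampled",
            meta={**proj.meta, "thinning_fraction": fraction, "subsample": i}))
    return out


def _rescale_to_target(proj: ProjectionSet, target_peak_counts: float) -> ProjectionSet:
    """Fix the count scale (detector sensitivity) to a target photopeak total."""
    tot = proj.photopeak.sum()
    scale = target_peak_counts / tot
    prov = {k: (v * scale if isinstance(v, np.ndarray) else v)
            for k, v in proj.provenance.items()}
    return ProjectionSet(counts=proj.counts * scale, geom=proj.geom,
                         windows=list(proj.windows), noise_state=proj.noise_state,
                         provenance=prov,
                         meta={**proj.meta,
                               "sensitivity": proj.meta.get("sensitivity", 1.0) * scale})


def _rc_table(result, rois, iterations=None):
    """RC per sphere ROI per saved iteration against the background ROI."""
    bkg = rois["background"]
    rows = []
    for it, img in enumerate(result.images, start=1):
        if iterations is not None and it not in iterations:
            continue
        bc = roi_counts(img, bkg.mask)
        for roi in rois.rois:
            if roi.role != "sphere" or not roi.mask.any():
                continue
            rc = recovery_coefficient(roi_counts(img, roi.mask), bc,
                                      roi.true_activity, bkg.true_activity)
            rows.append({"roi": roi.label, "iteration": it, "mode": result.mode,
                         "rc_percent": rc})
    return pd.DataFrame(rows)


def run_bias_experiment(cfg: ExperimentConfig | None = None,
                        modes=("conventional", "conventional_noscatter", "hybrid_mc")):
    """Bias isolation on the hot-sphere cylinder with noise-free data.

    Simulates low-noise triple-window projections of the 20 cm cylinder
    (10:1 spheres) with the MC engine, then reconstructs (a) conventional
    + TEW on the full data, (b) conventional with zero additive term on
    the primary-only split, (c) hybrid-MC on the full data. Returns
    (rc_tables dataframe, context dict).
    """
    cfg = cfg or ExperimentConfig()
    grid = cfg.grid()
    geom = cfg.geometry(grid)
    act, mu, rois = build_cylinder_sphere_phantom(grid)
    tcfg = TransportConfig(n_histories=cfg.n_histories_data,
                           rng_seed=mix_seed(cfg.master_seed, 1))
    proj = simulate_acquisition(act, mu, geom, cfg.psf, lu177_tew_windows(), tcfg)
    proj = _rescale_to_target(proj, cfg.target_total_peak_counts)

    rcfg = ReconConfig(n_iterations=cfg.n_iterations, n_subsets=cfg.n_subsets)
    tables = []
    results = {}
    for mode in modes:
        if mode == "conventional":
            res = reconstruct_conventional(proj, mu, geom, cfg.psf, rcfg, "tew")
        elif mode == "conventional_noscatter":
            primary = ProjectionSet(
                counts=proj.provenance["photopeak_primary"][None],
                geom=geom, windows=[proj.windows[0]], noise_state="expected",
                meta=proj.meta)
            res = reconstruct_conventional(primary, mu, geom, cfg.psf, rcfg, "none")
        elif mode == "hybrid_mc":
            ft = TransportConfig(n_histories=cfg.n_histories_forward,
                                 rng_seed=mix_seed(cfg.master_seed, 2))
            res = reconstruct_hybrid_mc(proj, mu, geom, cfg.psf, rcfg, ft)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        results[mode] = res
        tables.append(_rc_table(res, rois))
    table = pd.concat(tables, ignore_index=True)
    ctx = {"config": cfg.provenance(), "rois": rois, "projections": proj,
           "results": results,
           "mc_rel_err_peak_total": proj.meta.get("mc_rel_err_peak_total")}
    return table, ctx


def run_variance_experiment(cfg: ExperimentConfig | None = None,
                            roi_labels=None):
    """Paired multi-acquisition variance study on the NEMA-like phantom.

    Expected projections -> N Poisson realizations -> both reconstructions
    per realization (consuming the same sample, which makes the
    covariance terms meaningful) -> per-ROI count series -> Delta/SF
    tables. Returns (dataframe, context dict).
    """
    cfg = cfg or ExperimentConfig()
    grid = cfg.grid()
    geom = cfg.geometry(grid)
    act, mu, rois = build_nema_like_phantom(grid)
    tcfg = TransportConfig(n_histories=cfg.n_histories_data,
                           rng_seed=mix_seed(cfg.master_seed, 3))
    expected = simulate_acquisition(act, mu, geom, cfg.psf,
                                    lu177_tew_windows(), tcfg,
                                    keep_provenance=False)
    expected = _rescale_to_target(expected, cfg.target_total_peak_counts)
    realizations = poisson_realizations(expected, cfg.n_realizations,
                                        mix_seed(cfg.master_seed, 4))

    rcfg = ReconConfig(n_iterations=cfg.n_iterations, n_subsets=cfg.n_subsets,
                       save_every_iteration=False)
    labels = roi_labels or [r.label for r in rois.rois if r.mask.any()]
    series = {m: {lab: [] for lab in labels} for m in ("conventional", "hybrid_mc")}
    for i, proj in enumerate(realizations):
        conv = reconstruct_conventional(proj, mu, geom, cfg.psf, rcfg, "tew")
        ft = TransportConfig(n_histories=cfg.n_histories_forward,
                             rng_seed=mix_seed(cfg.master_seed, 5, i))
        hyb = reconstruct_hybrid_mc(proj, mu, geom, cfg.psf, rcfg, ft)
        for lab in labels:
            m = rois[lab].mask
            series["conventional"][lab].append(roi_counts(conv.final, m))
            series["hybrid_mc"][lab].append(roi_counts(hyb.final, m))

    rows = []
    for lab in labels:
        res = compare_variability(
            CountSeries(lab, series["conventional"][lab]),
            CountSeries(lab, series["hybrid_mc"][lab]))
        rows.append({
            "roi": lab, "n": res.n, "sigma_conv_percent": res.sigma_conv,
            "sigma_mc_percent": res.sigma_mc, "delta_percent": res.delta,
            "u_delta_percent": res.u_delta, "speedup": res.speedup,
            "u_speedup": res.u_speedup, "correlation": res.correlation})
    table = pd.DataFrame(rows)
    ctx = {"config": cfg.provenance(), "rois": rois, "series": series,
           "expected": expected}
    return table, ctx
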