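"""End-to-end automation: acquisition loop, full pipeline, run configuration.

``run_acquisition`` drives an instrument through the targeting sequence a
real automated cytology microscope executes: focus scan, autofocus to the
bright-spot plane, overlapping image grid, stitch, detect nuclei, keep the
most isolated ones, map pixels to stage coordinates, order a short route,
then acquire one spectrum per target in the focal plane (plus substrate
spectra from an empty region).

``run_full_pipeline`` composes acquisition (or ingest of pre-recorded
spectra) with the spectral pre-processing chain and cross-validated
classification, and writes the report bundle.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import (
    CVReport,
    PipelineSpec,
    all_pipelines,
    crossvalidate,
    marginal_relevance,
)
from .phantom import (
    CameraModel,
    SimulatedInstrument,
    SlideParams,
    SpectralPhantomParams,
    StageLimitError,
    default_axis,
    generate_spectrum_set,
)
from .preprocess import (
    CosmicRayReport,
    build_reference,
    build_substrate_reference,
    emsc_correct_set,
    quality_cull,
    remove_cosmic_rays,
    savitzky_golay_set,
)
from .spectral_core import SpectrumSet, crop_fingerprint, write_spectra
from .targeting import (
    AffineMap2D,
    ScanRangeError,
    TargetList,
    VarianceProfile,
    apply_laser_offset,
    autofocus,
    detect_bright_spots,
    fit_pixel_to_stage,
    order_route,
    select_isolated,
    stitch_grid,
    variance_metric,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "AcquisitionError",
    "run_acquisition",
    "simulate_run",
    "run_full_pipeline",
]


class AcquisitionError(RuntimeError):
    """A stage of the acquisition loop failed; carries diagnostics."""

    def __init__(self, message: str, profile: VarianceProfile | None = None) -> None:
        super().__init__(message)
        self.profile = profile


@dataclass
class RunConfig:
    """All tunable parameters of one run (defaults echo the study protocol)."""

    # focus scan
    z_min: float = -20.0  # µm
    z_max: float = 20.0  # µm
    z_step: float = 2.0  # µm
    # imaging grid
    grid_rows: int = 2
    grid_cols: int = 2
    overlap: float = 0.1  # fraction of the tile
    # targeting
    n_targets: int = 50
    detect_sigma: float = 4.0  # px
    detect_min_distance: int = 8  # px
    detect_prominence: float = 0.25
    laser_offset: tuple[float, float] = (0.0, 0.0)  # µm
    # acquisition
    t_acq: float = 10.0  # s per cell spectrum
    n_substrate: int = 20
    t_substrate: float = 30.0  # s per substrate spectrum
    # pre-processing
    cr_k_sigma: float = 8.0
    cr_max_width: int = 3
    reference_k: int = 50
    emsc_order: int = 5
    sg_window: int = 7
    sg_order: int = 3
    qc_threshold: float = 0.99
    fingerprint: tuple[float, float] = (600.0, 1800.0)  # cm^-1
    # classification
    cv_folds: int = 10
    models: str = "all"
    positive_class: str | None = None
    # phantom (simulate mode)
    n_per_class: int = 300
    n_reference_spectra: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")
        if not 0.0 < self.overlap < 0.5:
            raise ValueError("overlap must be in (0, 0.5)")
        if self.t_acq <= 0 or self.t_substrate <= 0:
            raise ValueError("acquisition times must be > 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and exceed sg_order")
        if not 0 < self.qc_threshold <= 1:
            raise ValueError("qc_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("laser_offset", "fingerprint"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def pipeline_specs(self) -> list[PipelineSpec]:
        if self.models == "all":
            return all_pipelines()
        wanted = {m.strip() for m in self.models.split(",")}
        specs = [s for s in all_pipelines() if s.name in wanted]
        if not specs:
            raise ValueError(f"no known models among {sorted(wanted)}")
        return specs

    def module_seeds(self) -> dict[str, int]:
        """Fan the master seed out to fixed per-module streams."""
        ss = np.random.SeedSequence(self.seed)
        names = ("slide_a", "slide_b", "instrument_a", "instrument_b",
                 "spectra", "reference", "cv")
        states = ss.generate_state(len(names))
        return {n: int(s) & 0x7FFFFFFF for n, s in zip(names, states)}


@dataclass
class RunManifest:
    """Traceable record of one acquisition run."""

    config: dict[str, Any]
    version: str = __version__
    focus: dict[str, float] = field(default_factory=dict)
    stage_visited: list[tuple[float, float]] = field(default_factory=list)
    targets: list[dict[str, Any]] = field(default_factory=list)
    skipped: list[dict[str, Any]] = field(default_factory=list)
    log: list[str] = field(default_factory=list)
    timing_s: dict[str, float] = field(default_factory=dict)

    def record(self, message: str) -> None:
        self.log.append(message)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))
        return path


def _focus_scan(instr: SimulatedInstrument, cfg: RunConfig,
                at: tuple[float, float]) -> VarianceProfile:
    zs = np.arange(cfg.z_min, cfg.z_max + 0.5 * cfg.z_step, cfg.z_step)
    instr.move_stage(*at)
    metric = []
    for z in zs:
        instr.set_z(float(z))
        metric.append(variance_metric(instr.snap_image()))
    return VarianceProfile(z=zs, metric=np.array(metric))


def _grid_positions(instr: SimulatedInstrument, cfg: RunConfig) -> list[tuple[float, float]]:
    h_px, w_px = instr.fov
    stride_x = w_px * instr.pixel_size * (1.0 - cfg.overlap)
    stride_y = h_px * instr.pixel_size * (1.0 - cfg.overlap)
    extent = instr.phantom.field_extent
    x0 = extent / 2.0 - stride_x * (cfg.grid_cols - 1) / 2.0
    y0 = extent / 2.0 + stride_y * (cfg.grid_rows - 1) / 2.0
    return [
        (x0 + c * stride_x, y0 - r * stride_y)
        for r in range(cfg.grid_rows)
        for c in range(cfg.grid_cols)
    ]


def run_acquisition(
    instr: SimulatedInstrument, cfg: RunConfig
) -> tuple[TargetList, SpectrumSet, RunManifest]:
    """Execute the full targeting-and-acquisition loop on one slide."""
    manifest = RunManifest(config=cfg.to_dict())
    t0 = time.perf_counter()

    centre = (instr.phantom.field_extent / 2.0, instr.phantom.field_extent / 2.0)
    profile = _focus_scan(instr, cfg, at=centre)
    try:
        focus = autofocus(profile)
    except ScanRangeError as exc:
        raise AcquisitionError(f"autofocus failed: {exc}", profile=profile) from exc
    manifest.focus = {"z_bright_spot": focus.z_bright_spot, "z_focus": focus.z_focus}
    manifest.record(f"autofocus: bright-spot {focus.z_bright_spot:+.1f} µm, "
                    f"focus {focus.z_focus:+.1f} µm")
    manifest.timing_s["autofocus"] = time.perf_counter() - t0

    # image the slide at the bright-spot plane
    t1 = time.perf_counter()
    instr.set_z(focus.z_bright_spot)
    tiles = []
    for pos in _grid_positions(instr, cfg):
        instr.move_stage(*pos)
        tiles.append(instr.snap_image())
    mosaic, offsets = stitch_grid(tiles, nominal_overlap=cfg.overlap)
    manifest.record(f"stitched {len(tiles)} tiles into {mosaic.shape} mosaic")

    candidates = detect_bright_spots(
        mosaic,
        sigma=cfg.detect_sigma,
        min_distance=cfg.detect_min_distance,
        prominence=cfg.detect_prominence,
    )
    manifest.record(f"detected {len(candidates)} bright-spot candidates")
    kept = select_isolated(candidates, cfg.n_targets) if len(candidates) else candidates
    manifest.timing_s["imaging"] = time.perf_counter() - t1

    if len(kept) == 0:
        targets = TargetList(stage_xy=np.empty((0, 2)), pixel_rc=np.empty((0, 2)))
        manifest.record("no candidates; skipping cell acquisition")
    else:
        # pixel->stage map from tile centres (mosaic position vs commanded stage)
        h_px, w_px = tiles[0].pixels.shape
        pix = offsets + np.array([(h_px - 1) / 2.0, (w_px - 1) / 2.0])
        stage = np.array([t.stage_xy for t in tiles])
        try:
            amap = fit_pixel_to_stage(pix, stage)
        except ValueError:
            # single-row grids are collinear; fall back to the nominal geometry
            px = tiles[0].pixel_size
            amap = AffineMap2D(
                linear=np.array([[0.0, px], [-px, 0.0]]),
                translation=stage[0] - np.array([[0.0, px], [-px, 0.0]]) @ pix[0],
            )
            manifest.record("affine fit underdetermined; using nominal stage geometry")
        manifest.record(f"pixel->stage affine RMS residual {amap.rms_residual:.3f} µm")

        stage_pts = amap(kept.points)
        routed = order_route(stage_pts, start=instr.position)
        routed.pixel_rc = kept.points[routed.order]
        targets = apply_laser_offset(routed, cfg.laser_offset)
        targets.pixel_rc = routed.pixel_rc

    # acquire the cell spectra in the focal plane
    t2 = time.perf_counter()
    instr.set_z(manifest.focus["z_focus"])
    spectra = []
    for i, (x, y) in enumerate(targets.stage_xy):
        try:
            instr.move_stage(float(x), float(y))
        except StageLimitError as exc:
            manifest.skipped.append({"index": i, "x_um": float(x), "y_um": float(y),
                                     "reason": str(exc)})
            manifest.record(f"skipped target {i}: {exc}")
            continue
        sp = instr.acquire_spectrum(cfg.t_acq)
        spectra.append(sp)
        manifest.targets.append({
            "index": i, "x_um": float(x), "y_um": float(y),
            "px_row": float(targets.pixel_rc[i][0]) if targets.pixel_rc is not None else None,
            "px_col": float(targets.pixel_rc[i][1]) if targets.pixel_rc is not None else None,
            "t_acq_s": cfg.t_acq, "spectrum_id": sp.id,
        })

    # substrate spectra from an empty corner of the slide
    substrate = []
    for _ in range(cfg.n_substrate):
        instr.move_stage(1.0, 1.0)
        substrate.append(instr.acquire_spectrum(cfg.t_substrate))
    manifest.timing_s["spectra"] = time.perf_counter() - t2
    manifest.stage_visited = [(float(x), float(y)) for x, y in instr.visited]

    all_spectra = spectra + substrate
    if all_spectra:
        out = SpectrumSet.from_spectra(
            [dataclasses.replace(s, id=f"{kind}{i:04d}")
             for kind, group in (("cell_", spectra), ("glass_", substrate))
             for i, s in enumerate(group)]
        )
        for i, m in enumerate(out.meta):
            if i < len(spectra):
                m.update(targets=manifest.targets[i]["index"],
                         x_um=manifest.targets[i]["x_um"],
                         y_um=manifest.targets[i]["y_um"], t_acq_s=cfg.t_acq,
                         kind="cell")
            else:
                m.update(t_acq_s=cfg.t_substrate, kind="substrate")
    else:  # pragma: no cover - empty phantom with zero substrate acquisitions
        out = SpectrumSet(axis=instr.axis, matrix=np.zeros((0, len(instr.axis))))
    return targets, out, manifest


# ---------------------------------------------------------------------------
# Full pipeline


def simulate_run(cfg: RunConfig, slide_params: SlideParams | None = None,
                 spectral_params: SpectralPhantomParams | None = None,
                 ) -> tuple[SpectrumSet, SpectrumSet, SpectrumSet]:
    """Generate the study's synthetic datasets: labelled cell spectra for the
    two classes, substrate (glass) spectra, and a clean reference dataset
    emulating acquisitions on a flat-background (CaF2-like) substrate."""
    p = spectral_params or SpectralPhantomParams()
    cam = CameraModel()
    axis = default_axis()
    seeds = cfg.module_seeds()
    classes = sorted(p.peaks)
    labels = [classes[0]] * cfg.n_per_class + [classes[-1]] * cfg.n_per_class
    cells = generate_spectrum_set(labels, p, cam, cfg.t_acq, axis, seed=seeds["spectra"])

    # substrate-only acquisitions from an empty region of the glass slide
    glass_p = dataclasses.replace(p, cosmic_ray_rate=0.0)
    rng = np.random.default_rng(seeds["instrument_a"])
    from .phantom import _generate_spectrum_with_truth
    from .spectral_core import SpectrumSet as _SpectrumSet

    rows = []
    for i in range(cfg.n_substrate):
        sp, _ = _generate_spectrum_with_truth(
            classes[0], glass_p, cam, cfg.t_substrate, axis,
            int(rng.integers(0, 2**31 - 1)), cr=0.0, cb=None, noise=True,
            id=f"glass{i:04d}")
        rows.append(sp.intensities)
    glass = _SpectrumSet(axis=axis, matrix=np.vstack(rows),
                         ids=[f"glass{i:04d}" for i in range(cfg.n_substrate)])

    # flat-substrate (CaF2-like) acquisitions of the high-grade line, used
    # only to construct the clean cell reference
    ref_p = dataclasses.replace(p, glass_humps=[], cosmic_ray_rate=0.0)
    positive = next((c for c in classes if "high" in c.lower()), classes[0])
    ref_set = generate_spectrum_set([positive] * cfg.n_reference_spectra, ref_p, cam,
                                    cfg.t_acq, axis, seed=seeds["reference"])
    return cells, glass, ref_set


def run_full_pipeline(
    cfg: RunConfig,
    outdir: str | Path | None = None,
    spectra: SpectrumSet | None = None,
    glass: SpectrumSet | None = None,
    reference_set: SpectrumSet | None = None,
) -> dict[str, Any]:
    """Acquisition/ingest -> pre-processing -> cross-validated classification.

    Returns a report bundle (dict of dataframes/arrays/reports); when
    ``outdir`` is given the bundle is also written as CSV/JSON artifacts.
    Any stage failure raises with the stage named; artifacts written before
    the failure are retained.
    """
    bundle: dict[str, Any] = {"config": cfg.to_dict()}
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        outpath.mkdir(parents=True, exist_ok=True)

    if spectra is None:
        spectra, glass, reference_set = simulate_run(cfg)
    if spectra.labels is None or any(l is None for l in spectra.labels):
        raise ValueError("classification stage: spectra must carry class labels")

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise AcquisitionError(f"pipeline stage {name!r} failed: {exc}") from exc

    # each class dataset is recorded and pre-processed as its own cohort:
    # cosmic-ray matching searches within the homogeneous dataset
    def _per_class_cosmic(ss):
        labels = np.asarray(ss.labels)
        cleaned_mat = ss.matrix.copy()
        flagged: list[list[int]] = [[] for _ in range(len(ss))]
        matched: list[str | None] = [None] * len(ss)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            sub_clean, rep = remove_cosmic_rays(ss.subset(idx), cfg.cr_k_sigma,
                                                cfg.cr_max_width)
            cleaned_mat[idx] = sub_clean.matrix
            for local, i in enumerate(idx):
                flagged[i] = rep.flagged[local]
                matched[i] = rep.matched_id[local]
        report = CosmicRayReport(flagged=flagged, matched_id=matched)
        return ss.with_matrix(cleaned_mat), report

    cleaned, cr_report = _stage("cosmic_rays", _per_class_cosmic, spectra)
    bundle["cosmic_ray_report"] = cr_report

    ref_source = reference_set if reference_set is not None else cleaned
    k = min(cfg.reference_k, len(ref_source))
    reference = _stage("reference", build_reference, ref_source, k)
    substrate = (_stage("substrate", build_substrate_reference, glass)
                 if glass is not None and len(glass) else None)

    corrected, emsc_results = _stage("emsc", emsc_correct_set, cleaned, reference,
                                     substrate, cfg.emsc_order)
    bundle["emsc_cr"] = np.array([r.cr for r in emsc_results])
    smoothed = _stage("savitzky_golay", savitzky_golay_set, corrected,
                      cfg.sg_window, cfg.sg_order)
    finger = _stage("fingerprint", crop_fingerprint, smoothed, *cfg.fingerprint)
    ref_f = crop_fingerprint(
        SpectrumSet(reference.axis, reference.intensities[None, :]), *cfg.fingerprint
    ).spectrum(0)
    culled, qc = _stage("quality_cull", quality_cull, finger, ref_f, cfg.qc_threshold)
    bundle["qc_report"] = qc
    bundle["processed"] = culled
    if len(culled) == 0:
        raise AcquisitionError("pipeline stage 'quality_cull' removed every spectrum")

    X = culled.matrix
    y = np.asarray(culled.labels)
    seeds = cfg.module_seeds()
    cv: CVReport = _stage("classification", crossvalidate, X, y,
                          cfg.pipeline_specs(), cfg.cv_folds, seeds["cv"],
                          cfg.positive_class)
    bundle["cv_report"] = cv
    bundle["metrics"] = cv.metrics_table()

    mr = marginal_relevance(X, y)
    bundle["mr_scores"] = pd.DataFrame(
        {"wavenumber_cm1": culled.axis.values, "mr_score": mr.score}
    )
    from sklearn.decomposition import PCA

    pca = PCA(n_components=3, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    bundle["pca_scores"] = pd.DataFrame(
        {"PC1": scores[:, 0], "PC2": scores[:, 1], "PC3": scores[:, 2], "label": y}
    )
    bundle["pca_loadings"] = pd.DataFrame(
        pca.components_.T, columns=["PC1", "PC2", "PC3"],
    ).assign(wavenumber_cm1=culled.axis.values)
    bundle["pca_explained_variance_ratio"] = pca.explained_variance_ratio_

    if outpath is not None:
        _write_bundle(bundle, culled, outpath)
    return bundle


def _write_bundle(bundle: dict[str, Any], processed: SpectrumSet, outdir: Path) -> None:
    write_spectra(processed, outdir / "processed_spectra.csv")
    qc = bundle["qc_report"]
    (outdir / "qc_report.json").write_text(json.dumps({
        "r": [round(float(v), 12) for v in qc.r],
        "retained": [bool(v) for v in qc.retained],
        "retention_fraction": round(qc.retention_fraction, 12),
        "cosmic_flagged_channels": bundle["cosmic_ray_report"].flagged,
    }, indent=1, sort_keys=True))
    bundle["mr_scores"].to_csv(outdir / "mr_scores.csv", index=False)
    bundle["pca_scores"].to_csv(outdir / "pca_scores.csv", index=False)
    bundle["pca_loadings"].to_csv(outdir / "pca_loadings.csv", index=False)
    bundle["metrics"].round(6).to_csv(outdir / "metrics.csv")
    cv = bundle["cv_report"]
    pd.DataFrame({k: pd.Series(v) for k, v in cv.fold_accuracy.items()}).to_csv(
        outdir / "fold_accuracies.csv", index_label="fold")
    report = {
        "explained_variance_ratio": [round(float(v), 12)
                                     for v in bundle["pca_explained_variance_ratio"]],
        "metrics": {name: [round(float(v), 12) for v in cv.metrics(name)]
                    for name in cv.confusion},
        "n_processed": len(processed),
        "retention_fraction": round(qc.retention_fraction, 12),
        "positive_class": cv.positive,
        "seed": bundle["config"]["seed"],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
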