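"""Synthetic multi-run BOLD sessions with ground truth.

Emulates the block-design acquisitions the method targets: an ABABABA
motor design (20 s blocks, TR 2.5 s, 56 volumes) and a visuomotor design
(10 s task / 20 s rest, TR 1 s, 160 volumes).  Voxels inside an elliptical
"brain" carry a baseline of 1000 arbitrary units; task regions add a
response template expressed in percent signal change (canonical, delayed,
transient onset/offset, negative, or none), each run adds an independent
random second-order polynomial drift and white Gaussian noise at a
configurable temporal SNR.  Runs listed as "bad" are generated with zero
task amplitude, emulating a run in which no task was performed.

A single seed drives a per-run seed tree, so sessions are bit-reproducible
and adding regions does not perturb the noise streams.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Sequence

import numpy as np
import yaml

from .data_io import DesignSpec, RunSeries, Session, save_map, save_run
from .glm import HrfKernel, canonical_hrf

#: shape-label codes written to the ground-truth label grid
SHAPE_LABELS = {"none": 0, "canonical": 1, "delayed": 2,
                "transient_onset_offset": 3, "negative": 4}


@dataclasses.dataclass
class RegionSpec:
    """A set of voxels sharing one response shape and amplitude."""

    voxels: np.ndarray            # boolean 3D grid
    shape_kind: str = "canonical"
    amplitude: float = 2.0        # percent signal change at template peak
    delay: float = 2.5            # seconds, for "delayed"
    transient_width: float = 2.0  # seconds, for "transient_onset_offset"

    def __post_init__(self) -> None:
        if self.shape_kind not in SHAPE_LABELS:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        self.voxels = np.asarray(self.voxels).astype(bool)


@dataclasses.dataclass
class SynthConfig:
    grid: tuple[int, int, int] = (24, 24, 12)
    design_kind: str = "motor_ababab"
    tr: float | None = None       # default from the design kind
    n_runs: int = 10
    regions: list[RegionSpec] = dataclasses.field(default_factory=list)
    tsnr_target: float | None = 100.0
    noise_sd: float | None = None  # overrides tsnr_target when set
    drift_coeff_sd: tuple[float, float, float] = (10.0, 20.0, 20.0)
    ar1: float = 0.0
    baseline: float = 1000.0
    bad_runs: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("need at least 2 runs")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        occupied = np.zeros(self.grid, dtype=bool)
        for r in self.regions:
            if r.voxels.shape != tuple(self.grid):
                raise ValueError("region grid does not match config grid")
            if (occupied & r.voxels).any():
                raise ValueError("regions must be disjoint")
            occupied |= r.voxels
        for b in self.bad_runs:
            if not 0 <= b < self.n_runs:
                raise ValueError("bad run index out of range")

    @property
    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        if self.tsnr_target is None:
            raise ValueError("set either noise_sd or tsnr_target")
        return self.baseline / self.tsnr_target


@dataclasses.dataclass
class GroundTruth:
    active_mask: np.ndarray            # union of non-"none" regions
    shape_label: np.ndarray            # int grid, SHAPE_LABELS codes
    noiseless_templates: list[np.ndarray]  # per region, percent units, (T,)
    bad_runs: list[int]
    brain_mask: np.ndarray


def make_design(kind: str, tr: float | None = None):
    """Standard study designs: returns (DesignSpec, T, tr).

    * ``motor_ababab`` — four rest and three 20 s task blocks alternating
      (ABABABA), 140 s total; TR 2.5 s gives 56 volumes.
    * ``visuomotor`` — 10 s initial rest, then five 10 s task / 20 s rest
      cycles, 160 s total; TR 1 s gives 160 volumes.
    """
    if kind == "motor_ababab":
        tr = 2.5 if tr is None else float(tr)
        design = DesignSpec(block_onsets=(20.0, 60.0, 100.0),
                            block_durations=(20.0, 20.0, 20.0),
                            total_duration=140.0, label=kind)
    elif kind == "visuomotor":
        tr = 1.0 if tr is None else float(tr)
        design = DesignSpec(block_onsets=(10.0, 40.0, 70.0, 100.0, 130.0),
                            block_durations=(10.0,) * 5,
                            total_duration=160.0, label=kind)
    else:
        raise ValueError(f"unknown design kind {kind!r}")
    T = int(round(design.total_duration / tr))
    return design, T, tr


def response_template(region: RegionSpec, design: DesignSpec, T: int,
                      tr: float, hrf: HrfKernel | None = None) -> np.ndarray:
    """Noiseless response time course of a region, in percent signal change.

    The shape-specific stimulus train is convolved with the HRF on the
    kernel's fine grid, sampled at the volume times, peak-normalised and
    scaled to the region amplitude.
    """
    if hrf is None:
        hrf = canonical_hrf()
    dt = hrf.dt
    n_fine = int(np.ceil(T * tr / dt)) + 1
    tt = np.arange(n_fine) * dt
    stim = np.zeros(n_fine)
    kind = region.shape_kind
    if kind == "none":
        return np.zeros(T)
    if kind in ("canonical", "negative"):
        for onset, dur in zip(design.block_onsets, design.block_durations):
            stim[(tt >= onset) & (tt < onset + dur)] = 1.0
    elif kind == "delayed":
        for onset, dur in zip(design.block_onsets, design.block_durations):
            o = onset + region.delay
            stim[(tt >= o) & (tt < o + dur)] = 1.0
    elif kind == "transient_onset_offset":
        w = region.transient_width
        for onset, dur in zip(design.block_onsets, design.block_durations):
            for edge in (onset, onset + dur):
                stim[(tt >= edge) & (tt < edge + w)] = 1.0
    conv = np.convolve(stim, hrf.samples)[:n_fine]
    idx = np.clip(np.round(np.arange(T) * tr / dt).astype(int), 0, n_fine - 1)
    tc = conv[idx]
    peak = np.abs(tc).max()
    if peak > 0:
        tc = tc / peak
    tc = tc * region.amplitude
    if kind == "negative":
        tc = -tc
    return tc


def ellipsoid_mask(grid: Sequence[int],
                   radii: Sequence[float] | None = None) -> np.ndarray:
    """Axis-aligned ellipsoid centred in the grid (the synthetic "brain")."""
    grid = tuple(grid)
    if radii is None:
        radii = tuple((g - 2) / 2.0 for g in grid)
    idx = np.indices(grid, dtype=np.float64)
    c = [(g - 1) / 2.0 for g in grid]
    d = sum(((idx[i] - c[i]) / radii[i]) ** 2 for i in range(3))
    return d <= 1.0


def block_region(grid: Sequence[int], center: Sequence[int],
                 size: Sequence[int], **kwargs) -> RegionSpec:
    """Axis-aligned block region (unambiguous ground truth)."""
    vox = np.zeros(tuple(grid), dtype=bool)
    sl = tuple(slice(c - s // 2, c - s // 2 + s) for c, s in zip(center, size))
    vox[sl] = True
    return RegionSpec(voxels=vox, **kwargs)


def generate_session(config: SynthConfig):
    """Generate a reproducible multi-run session plus its ground truth.

    Per run r and brain voxel v:
    signal(t) = 1000 * (1 + template_v(t)/100) + drift_r(t) + noise(0, sd),
    with drift_r a random second-order polynomial in normalised time
    (coefficients ~ Normal(0, drift_coeff_sd), fresh per run) and noise
    independent across runs, voxels and time (optionally AR(1)).
    """
    design, T, tr = make_design(config.design_kind, config.tr)
    hrf = canonical_hrf()
    brain = ellipsoid_mask(config.grid)
    for r in config.regions:
        if (r.voxels & ~brain).any():
            raise ValueError("regions must lie inside the brain ellipsoid")

    templates = [response_template(r, design, T, tr, hrf)
                 for r in config.regions]
    # percent-signal template per brain voxel (mostly zero rows)
    pct = np.zeros(config.grid + (T,))
    for region, tc in zip(config.regions, templates):
        pct[region.voxels] = tc

    noise_sd = config.resolved_noise_sd
    tn = np.arange(T, dtype=np.float64) / max(T - 1, 1)
    poly = np.vstack([np.ones(T), tn, tn * tn])

    ss = np.random.SeedSequence(config.seed)
    run_seeds = ss.spawn(config.n_runs)
    runs: list[RunSeries] = []
    n_brain = int(brain.sum())
    for r in range(config.n_runs):
        drift_ss, noise_ss = run_seeds[r].spawn(2)
        rng_d = np.random.default_rng(drift_ss)
        rng_n = np.random.default_rng(noise_ss)
        data = np.zeros(config.grid + (T,))
        signal = np.broadcast_to(config.baseline, (n_brain, T)).copy()
        if r not in config.bad_runs:
            signal += config.baseline * pct[brain] / 100.0
        coeffs = rng_d.normal(0.0, config.drift_coeff_sd)
        signal += coeffs @ poly
        noise = rng_n.normal(0.0, noise_sd, size=(n_brain, T))
        if config.ar1:
            phi = config.ar1
            noise *= np.sqrt(1.0 - phi * phi)
            for t in range(1, T):
                noise[:, t] += phi * noise[:, t - 1]
        data[brain] = signal + noise
        runs.append(RunSeries(data=data, tr=tr, run_id=r))

    active = np.zeros(config.grid, dtype=bool)
    labels = np.zeros(config.grid, dtype=np.int16)
    for region in config.regions:
        labels[region.voxels] = SHAPE_LABELS[region.shape_kind]
        if region.shape_kind != "none":
            active |= region.voxels
    session = Session(runs=runs, mask=brain, design=design)
    truth = GroundTruth(active_mask=active, shape_label=labels,
                        noiseless_templates=templates,
                        bad_runs=sorted(config.bad_runs), brain_mask=brain)
    return session, truth


def write_session(session: Session, truth: GroundTruth, out_dir: str,
                  config: SynthConfig | None = None) -> str:
    """Write runs, mask, ground truth and a manifest; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    run_files = []
    for r in session.runs:
        name = f"run_{r.run_id:02d}.nii.gz"
        save_run(r, os.path.join(out_dir, name))
        run_files.append(name)
    ref = session.runs[0]
    save_map(session.mask.astype(np.float32), ref,
             os.path.join(out_dir, "mask.nii.gz"))
    save_map(truth.active_mask.astype(np.float32), ref,
             os.path.join(out_dir, "truth_active_mask.nii.gz"))
    save_map(truth.shape_label.astype(np.float32), ref,
             os.path.join(out_dir, "truth_shape_label.nii.gz"))
    manifest = {
        "runs": run_files,
        "tr_seconds": session.tr,
        "mask": "mask.nii.gz",
        "design": {
            "onsets": list(session.design.block_onsets),
            "durations": list(session.design.block_durations),
            "total_duration": session.design.total_duration,
            "label": session.design.label,
        },
    }
    manifest_path = os.path.join(out_dir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    if config is not None:
        params = dataclasses.asdict(config)
        params["regions"] = [
            {"shape_kind": r.shape_kind, "amplitude": r.amplitude,
             "delay": r.delay, "transient_width": r.transient_width,
             "n_voxels": int(r.voxels.sum())}
            for r in config.regions]
        params["bad_runs"] = list(config.bad_runs)
        with open(os.path.join(out_dir, "params.json"), "w") as fh:
            json.dump(params, fh, indent=2, default=str)
    return manifest_path


def preset(name: str, seed: int = 0, **overrides) -> SynthConfig:
    """Named study scenarios used throughout the tests and examples.

    Amplitudes follow typical ultra-high-field motor/visual cortex signal
    changes (a few percent); temporal SNR defaults to 100, a mid-range
    value for 7 T gray matter at this voxel size.

    * ``two_run`` — minimal two-run session, one canonical region.
    * ``motor_basic`` — 10-run motor session, one strong canonical region.
    * ``pure_noise`` — 10 runs, drift + noise only (null calibration).
    * ``one_bad_run`` — 10 runs at typical 7 T motor-cortex contrast
      (3 %, tSNR 100) with run 6 generated at zero amplitude.
    * ``all_good`` — as ``one_bad_run`` but with no bad run.
    * ``one_bad_run_low_cnr`` / ``all_good_low_cnr`` — the same scenarios
      at barely-detectable contrast (1 %, tSNR 50), where the per-pair
      inter-run correlation is ~0.05 and activation foci sit below the
      top-percentile noise floor.
    * ``delayed_response`` — response generated 2.5 s (1 TR) later than
      the task timing, for shift-sensitivity experiments.
    * ``transient_mixed`` — one canonical and one transient onset/offset
      region, for modified-response-shape experiments.
    * ``split_half_20`` — 20-run motor session with stable activation.
    * ``recovery`` — 1 % signal at tSNR 400, where per-pair detection is
      near-certain for active voxels (the per-pair inter-run correlation
      is ~0.75, giving pairwise t well above the p < 0.001 cut).
    """
    presets: dict[str, dict] = {
        "two_run": dict(
            grid=(16, 16, 6), n_runs=2, tsnr_target=100.0,
            regions_spec=[((8, 8, 3), (4, 4, 2), "canonical", 5.0)]),
        "motor_basic": dict(
            grid=(24, 24, 12), n_runs=10, tsnr_target=100.0,
            regions_spec=[((12, 12, 6), (8, 8, 4), "canonical", 5.0)]),
        "pure_noise": dict(
            grid=(26, 26, 10), n_runs=10, tsnr_target=100.0, regions_spec=[]),
        "one_bad_run": dict(
            grid=(24, 24, 12), n_runs=10, tsnr_target=100.0, bad_runs=(6,),
            regions_spec=[((12, 12, 6), (8, 8, 4), "canonical", 3.0)]),
        "all_good": dict(
            grid=(24, 24, 12), n_runs=10, tsnr_target=100.0,
            regions_spec=[((12, 12, 6), (8, 8, 4), "canonical", 3.0)]),
        "one_bad_run_low_cnr": dict(
            grid=(40, 40, 16), n_runs=10, tsnr_target=50.0, bad_runs=(6,),
            regions_spec=[((20, 20, 8), (10, 10, 6), "canonical", 1.0)]),
        "all_good_low_cnr": dict(
            grid=(40, 40, 16), n_runs=10, tsnr_target=50.0,
            regions_spec=[((20, 20, 8), (10, 10, 6), "canonical", 1.0)]),
        "delayed_response": dict(
            grid=(32, 32, 8), n_runs=10, tsnr_target=100.0,
            regions_spec=[((16, 16, 4), (6, 6, 4), "delayed", 5.0)]),
        "transient_mixed": dict(
            grid=(24, 24, 12), n_runs=10, tsnr_target=100.0,
            regions_spec=[((8, 12, 6), (6, 6, 4), "canonical", 5.0),
                          ((17, 12, 6), (5, 5, 4), "transient_onset_offset", 5.0)]),
        "split_half_20": dict(
            grid=(24, 24, 12), n_runs=20, tsnr_target=100.0,
            regions_spec=[((12, 12, 6), (8, 8, 4), "canonical", 5.0)]),
        "recovery": dict(
            grid=(24, 24, 12), n_runs=10, tsnr_target=400.0,
            regions_spec=[((12, 12, 6), (8, 8, 4), "canonical", 1.0)]),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(presets)}")
    spec = dict(presets[name])
    regions_spec = spec.pop("regions_spec")
    spec.update(overrides)
    grid = spec["grid"]
    regions = [block_region(grid, center, size, shape_kind=kind,
                            amplitude=amp)
               for center, size, kind, amp in regions_spec]
    spec.setdefault("regions", regions)
    return SynthConfig(seed=seed, **spec)
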