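"""Reading, writing and session assembly for multi-run fMRI data.

A *session* is an ordered collection of co-registered 4D runs acquired with
identical task timing on a common voxel grid.  All volumes are exchanged as
NIfTI-1 files; session composition is described by a small YAML/JSON
manifest.  Runs are assumed to be realigned already (motion correction,
slice timing and inter-run registration happen upstream) so that spatial
correspondence across runs is by identical voxel index.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: minimum number of volumes accepted when loading a run from disk
MIN_VOLUMES = 8


@dataclasses.dataclass
class DesignSpec:
    """Block-design task timing shared by every run of a session.

    Onsets and durations are in seconds from the start of the run.
    """

    block_onsets: tuple[float, ...]
    block_durations: tuple[float, ...]
    total_duration: float
    label: str = ""

    def __post_init__(self) -> None:
        self.block_onsets = tuple(float(o) for o in self.block_onsets)
        self.block_durations = tuple(float(d) for d in self.block_durations)
        if len(self.block_onsets) != len(self.block_durations):
            raise ValueError("onsets and durations must have equal length")
        if any(b <= a for a, b in zip(self.block_onsets, self.block_onsets[1:])):
            raise ValueError("block onsets must be strictly increasing")
        for o, d in zip(self.block_onsets, self.block_durations):
            if o + d > self.total_duration + 1e-9:
                raise ValueError(
                    f"block at {o}s with duration {d}s exceeds the "
                    f"run duration of {self.total_duration}s"
                )

    @property
    def n_blocks(self) -> int:
        return len(self.block_onsets)


@dataclasses.dataclass
class RunSeries:
    """One run's 4D signal: an (X, Y, Z, T) grid plus acquisition metadata."""

    data: np.ndarray
    tr: float
    run_id: int
    source_path: str = ""
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"run data must be 4D, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def copy_with(self, data: np.ndarray) -> "RunSeries":
        return RunSeries(data=data, tr=self.tr, run_id=self.run_id,
                         source_path=self.source_path, affine=self.affine.copy())


@dataclasses.dataclass
class Session:
    """Ordered runs on a common grid, with a brain mask and design timing."""

    runs: list[RunSeries]
    mask: np.ndarray
    design: DesignSpec

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("a session requires at least two runs")
        shape = self.runs[0].data.shape
        tr = self.runs[0].tr
        for r in self.runs[1:]:
            if r.data.shape[:3] != shape[:3]:
                raise ValueError("inconsistent spatial grid across runs")
            if r.n_volumes != shape[3]:
                raise ValueError("inconsistent volume count across runs")
            if abs(r.tr - tr) > 1e-9:
                raise ValueError("inconsistent TR across runs")
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != shape[:3]:
            raise ValueError("mask shape does not match the run grid")
        if not self.mask.any():
            raise ValueError("empty mask")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def tr(self) -> float:
        return self.runs[0].tr

    @property
    def n_volumes(self) -> int:
        return self.runs[0].n_volumes

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.runs[0].spatial_shape

    def subset(self, positions: Sequence[int]) -> "Session":
        """A new session of the runs at the given positions, renumbered.

        Run ids are re-assigned to 0..len-1 so that positional indexing and
        run ids stay consistent within the new session; provenance remains
        available through each run's ``source_path``.
        """
        runs = []
        for i, p in enumerate(positions):
            r = self.runs[p]
            runs.append(RunSeries(data=r.data, tr=r.tr, run_id=i,
                                  source_path=r.source_path,
                                  affine=r.affine.copy()))
        return Session(runs=runs, mask=self.mask.copy(), design=self.design)


def load_run(path: str, run_id: int, tr: float | None = None) -> RunSeries:
    """Load a 4D NIfTI run; non-finite voxel values are zero-filled."""
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    if data.shape[3] < MIN_VOLUMES:
        raise ValueError(f"{path}: run has fewer than {MIN_VOLUMES} volumes")
    bad = ~np.isfinite(data)
    if bad.any():
        logger.warning("%s: zero-filled %d non-finite values", path, int(bad.sum()))
        data[bad] = 0.0
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return RunSeries(data=data, tr=float(tr), run_id=run_id,
                     source_path=str(path), affine=np.asarray(img.affine))


def _read_manifest(path: str) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def load_session(manifest: str) -> Session:
    """Assemble a :class:`Session` from a YAML/JSON manifest.

    The manifest lists the run files (in acquisition order), the TR in
    seconds, the block design and, optionally, a brain-mask file.  Relative
    paths are resolved against the manifest's directory.  When no mask is
    given one is derived with :func:`compute_brain_mask`.
    """
    doc = _read_manifest(manifest)
    base = os.path.dirname(os.path.abspath(manifest))

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    run_paths = [_resolve(p) for p in doc["runs"]]
    if len(run_paths) < 2:
        raise ValueError("manifest must list at least two runs")
    for p in run_paths:
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    tr = float(doc["tr_seconds"])
    d = doc["design"]
    design = DesignSpec(block_onsets=tuple(d["onsets"]),
                        block_durations=tuple(d["durations"]),
                        total_duration=float(d["total_duration"]),
                        label=str(d.get("label", "")))
    runs = [load_run(p, run_id=i, tr=tr) for i, p in enumerate(run_paths)]
    if doc.get("mask"):
        mask_img = nib.load(_resolve(doc["mask"]))
        mask = np.asarray(mask_img.dataobj) > 0
    else:
        probe = Session(runs=runs, mask=np.ones(runs[0].spatial_shape, bool),
                        design=design)
        mask = compute_brain_mask(probe)
    return Session(runs=runs, mask=mask, design=design)


def compute_brain_mask(session_or_run: Session | RunSeries,
                       intensity_quantile: float = 0.25) -> np.ndarray:
    """Derive a brain mask from signal intensity.

    A voxel is in-brain iff its temporal mean reaches the given quantile of
    the nonzero temporal means *and* its time course is not constant.  For a
    session the temporal mean is averaged over runs and every run must show
    temporal variance.  Intended as a fallback when no mask is provided;
    acquired data normally comes with an anatomically derived mask.
    """
    if isinstance(session_or_run, Session):
        runs = session_or_run.runs
    else:
        runs = [session_or_run]
    means = np.mean([r.data.mean(axis=3) for r in runs], axis=0)
    sd_ok = np.all([r.data.std(axis=3) > 0 for r in runs], axis=0)
    nz = means[means != 0]
    if nz.size == 0:
        raise ValueError("empty mask: input volume is identically zero")
    thr = np.quantile(nz, intensity_quantile)
    mask = (means >= thr) & (means != 0) & sd_ok
    if not mask.any():
        raise ValueError("empty mask: no voxel passed the intensity/variance rule")
    return mask


def save_map(map3d: np.ndarray, reference: RunSeries, path: str) -> None:
    """Write a 3D map as NIfTI-1 using the reference run's geometry."""
    map3d = np.asarray(map3d)
    if map3d.shape != reference.spatial_shape:
        raise ValueError(
            f"map shape {map3d.shape} does not match reference "
            f"{reference.spatial_shape}")
    img = nib.Nifti1Image(map3d.astype(np.float32), reference.affine)
    img.header.set_zooms(nib.load(reference.source_path).header.get_zooms()[:3]
                         if reference.source_path and os.path.exists(reference.source_path)
                         else img.header.get_zooms())
    nib.save(img, path)


def save_run(run: RunSeries, path: str) -> None:
    """Write a 4D run as NIfTI-1, carrying the TR in the header."""
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)


def write_qc_report(report, path: str) -> None:
    """Serialize a bad-run report as TSV.

    One row per (pass, tested run) with the Welch statistics and the
    decision; the final good-run list is appended as a comment footer.
    Run indices are 0-based manifest positions.
    """
    rows = [{
        "pass": rec.pass_index,
        "run_id": rec.run_id,
        "welch_t": rec.welch_t,
        "welch_dof": rec.welch_dof,
        "p_one_sided": rec.p_one_sided,
        "alpha_corrected": rec.alpha_corrected,
        "decision": rec.decision,
    } for rec in report.passes]
    df = pd.DataFrame(rows, columns=["pass", "run_id", "welch_t", "welch_dof",
                                     "p_one_sided", "alpha_corrected", "decision"])
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write("# good_runs: " + ",".join(str(r) for r in report.good_runs) + "\n")


def read_qc_report(path: str) -> tuple[pd.DataFrame, list[int]]:
    """Parse a QC TSV back into the per-pass table and the good-run list."""
    good: list[int] = []
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("# good_runs:"):
            payload = line.split(":", 1)[1].strip()
            good = [int(x) for x in payload.split(",") if x != ""]
        else:
            body.append(line)
    from io import StringIO
    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    return df, good
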