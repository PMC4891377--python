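"""Reference GLM on identically preprocessed data, and fit-quality maps.

A single-regressor general linear model (canonical double-gamma HRF
convolved with the task boxcar, plus an intercept) fitted per run to the
same polynomial-detrended data the inter-run analysis uses.  Voxelwise
coefficients of determination from both approaches feed the normalised
comparison map

    r_UG = (R2_unbiased - R2_glm) / (R2_unbiased + R2_glm),

which is positive where run-to-run consistency explains the signal better
than the canonical model — the signature of delayed or transient responses.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, stats

from .core import PairStatSet, _ols_slope
from .data_io import DesignSpec, RunSeries, Session

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class HrfKernel:
    """Sampled hemodynamic impulse response, peak-normalised to 1."""

    samples: np.ndarray
    dt: float
    length: float


@dataclasses.dataclass
class GlmResult:
    beta: np.ndarray
    t: np.ndarray
    r2: np.ndarray
    dof: int


@dataclasses.dataclass
class Cluster:
    label: int
    size: int
    voxels: np.ndarray      # (size, 3) integer indices
    centroid: tuple[float, float, float]


def canonical_hrf(dt: float = 0.1, length: float = 32.0,
                  peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  ratio: float = 6.0) -> HrfKernel:
    """Canonical double-gamma HRF (SPM convention), sampled every ``dt`` s.

    g(t; shape peak_delay, scale 1) - g(t; shape undershoot_delay, scale 1)
    / ratio, on [0, length], normalised to unit peak.  The response rises to
    a maximum near 5 s and is followed by a shallow negative undershoot.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length + dt / 2, dt)
    h = stats.gamma.pdf(t, peak_delay) - stats.gamma.pdf(t, undershoot_delay) / ratio
    h = h / h.max()
    return HrfKernel(samples=h, dt=dt, length=length)


def block_regressor(design: DesignSpec, T: int, tr: float,
                    hrf: HrfKernel | None = None) -> np.ndarray:
    """Mean-centred task regressor at the volume grid.

    The task boxcar is built on the HRF's fine time grid, convolved with
    the kernel, sampled at the volume times v*tr and mean-centred.
    """
    if hrf is None:
        hrf = canonical_hrf()
    if design.block_onsets and (design.block_onsets[-1]
                                + design.block_durations[-1]) > T * tr + 1e-9:
        raise ValueError("design exceeds the run duration")
    dt = hrf.dt
    n_fine = int(np.ceil(T * tr / dt)) + 1
    tt = np.arange(n_fine) * dt
    box = np.zeros(n_fine)
    for onset, dur in zip(design.block_onsets, design.block_durations):
        box[(tt >= onset) & (tt < onset + dur)] = 1.0
    conv = np.convolve(box, hrf.samples)[:n_fine]
    peak = np.abs(conv).max()
    if peak > 0:
        conv = conv / peak
    idx = np.clip(np.round(np.arange(T) * tr / dt).astype(int), 0, n_fine - 1)
    reg = conv[idx]
    return reg - reg.mean()


def glm_fit_run(run: RunSeries, regressor: np.ndarray,
                mask: np.ndarray) -> GlmResult:
    """Voxelwise OLS of the run on [intercept, regressor]."""
    regressor = np.asarray(regressor, dtype=np.float64)
    if regressor.size != run.n_volumes:
        raise ValueError("regressor length must equal the volume count")
    if np.ptp(regressor) == 0:
        raise ValueError("constant regressor")
    mask = np.asarray(mask).astype(bool)
    y = run.data[mask]
    x = np.broadcast_to(regressor, y.shape)
    beta_v, t_v, r2_v, _, dof = _ols_slope(x, y)
    shape = run.spatial_shape

    def _full(v):
        out = np.zeros(shape)
        out[mask] = v
        return out

    return GlmResult(beta=_full(beta_v), t=_full(t_v), r2=_full(r2_v), dof=dof)


def glm_session(session: Session, regressor: np.ndarray | None = None,
                hrf: HrfKernel | None = None,
                good_runs: Iterable[int] | None = None) -> GlmResult:
    """Per-run GLM fits averaged voxelwise across (good) runs.

    The model is fitted to each run separately — matching the pairwise
    structure of the inter-run analysis and keeping residual dof comparable
    — and beta, t and R2 are averaged across the included runs.
    """
    if regressor is None:
        regressor = block_regressor(session.design, session.n_volumes,
                                    session.tr, hrf)
    ids = set(good_runs) if good_runs is not None else None
    fits = [glm_fit_run(r, regressor, session.mask) for r in session.runs
            if ids is None or r.run_id in ids]
    if not fits:
        raise ValueError("no runs selected")
    return GlmResult(beta=np.mean([f.beta for f in fits], axis=0),
                     t=np.mean([f.t for f in fits], axis=0),
                     r2=np.mean([f.r2 for f in fits], axis=0),
                     dof=fits[0].dof)


def r2_unbiased(pairs: PairStatSet, good_runs: Iterable[int],
                pooled: bool = False) -> np.ndarray:
    """Voxelwise R2 of the inter-run fits over good-run pairs.

    By default the mean over pairs of each pair fit's R2 (1 - SSres/SStot);
    with ``pooled=True`` residual and total sums of squares are combined
    across pairs before forming the ratio.
    """
    sel = pairs.select(good_runs)
    if len({r for p in sel for r in (p.j, p.k)}) < 2:
        raise ValueError("requires at least 2 good runs")
    if not pooled:
        return np.mean([p.r2 for p in sel], axis=0)
    ss_tot = np.sum([p.ss_tot for p in sel], axis=0)
    ss_res = np.sum([(1.0 - p.r2) * p.ss_tot for p in sel], axis=0)
    out = np.zeros_like(ss_tot)
    ok = ss_tot > 0
    out[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    return out


def rug_map(r2_unb: np.ndarray, r2_glm: np.ndarray) -> np.ndarray:
    """Normalised R2 difference (R2_U - R2_G)/(R2_U + R2_G), in [-1, 1].

    Voxels where both R2 are zero map to 0.
    """
    r2_unb = np.asarray(r2_unb, dtype=np.float64)
    r2_glm = np.asarray(r2_glm, dtype=np.float64)
    if r2_unb.shape != r2_glm.shape:
        raise ValueError("R2 maps must share a shape")
    total = r2_unb + r2_glm
    out = np.zeros_like(total)
    ok = total > 0
    out[ok] = (r2_unb[ok] - r2_glm[ok]) / total[ok]
    return out


def positive_rug_clusters(rug: np.ndarray, mask: np.ndarray,
                          min_size: int = 10) -> list[Cluster]:
    """Connected components (26-connectivity) of {r_UG > 0} in the mask.

    Clusters smaller than ``min_size`` voxels are dropped; the remainder is
    sorted by size, largest first.
    """
    mask = np.asarray(mask).astype(bool)
    pos = (np.asarray(rug) > 0) & mask
    labels, n = ndimage.label(pos, structure=np.ones((3, 3, 3), dtype=int))
    clusters: list[Cluster] = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] < min_size:
            continue
        clusters.append(Cluster(label=lab, size=idx.shape[0], voxels=idx,
                                centroid=tuple(idx.mean(axis=0))))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


@dataclasses.dataclass
class RoiTimecourse:
    """Spatial mean/sd time courses over a cubic ROI, per run and averaged."""

    run_means: np.ndarray   # (N, T)
    run_sds: np.ndarray     # (N, T)
    mean: np.ndarray        # (T,), average of run means across runs
    n_voxels: int


def roi_mean_timecourse(session: Session, center: Sequence[int],
                        edge: int = 5) -> RoiTimecourse:
    """Average time course of a cubic ROI centred on a voxel.

    The cube of side ``edge`` is clipped at the volume boundary (logged).
    ``edge=1`` returns the centre voxel's own time course.
    """
    shape = session.spatial_shape
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= s for c, s in zip(center, shape)):
        raise ValueError(f"ROI centre {center} outside volume {shape}")
    half = edge // 2
    sl = []
    clipped = False
    for c, s in zip(center, shape):
        lo, hi = c - half, c - half + edge
        if lo < 0 or hi > s:
            clipped = True
        sl.append(slice(max(lo, 0), min(hi, s)))
    if clipped:
        logger.info("ROI cube at %s clipped to volume bounds", center)
    run_means, run_sds = [], []
    for r in session.runs:
        block = r.data[sl[0], sl[1], sl[2], :].reshape(-1, session.n_volumes)
        run_means.append(block.mean(axis=0))
        run_sds.append(block.std(axis=0))
    run_means = np.asarray(run_means)
    n_vox = int(np.prod([s.stop - s.start for s in sl]))
    return RoiTimecourse(run_means=run_means, run_sds=np.asarray(run_sds),
                         mean=run_means.mean(axis=0), n_voxels=n_vox)
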