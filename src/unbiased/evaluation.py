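"""Assessment experiments: split-half congruence and shift sensitivity.

Two experiments probe the behaviour of the inter-run consistency analysis
against the reference GLM:

* **Split-half congruence** — runs are split by acquisition order into the
  odd and the even runs, each half is analysed separately, and the overlap
  of supra-threshold voxels between halves (Dice coefficient) is tabulated
  over reliability thresholds 0..100 % in 5 % steps.  At each threshold the
  GLM comparison mask is count-matched: the same number of voxels with the
  largest GLM t values is selected, so Dice values are comparable.

* **Shift sensitivity** — the same circular temporal shift is applied to
  every (detrended) run and both analyses are re-run.  Because inter-run
  regression only pairs identically-indexed time points, a global circular
  shift leaves pairwise slopes and t values mathematically unchanged,
  whereas the GLM's fit to a fixed regressor degrades with misalignment.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ReliabilityMap, all_pair_fits, reliability_map
from .data_io import Session
from .glm import GlmResult, block_regressor, glm_session
from .pipeline import run_unbiased
from .preprocess import detrend_session, shift_session

logger = logging.getLogger(__name__)

#: congruence label codes
CONGRUENCE_NONE, CONGRUENCE_BOTH, CONGRUENCE_ODD, CONGRUENCE_EVEN = 0, 1, 2, 3


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a|+|b|); two empty masks count as 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        logger.info("dice of two empty masks defined as 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def match_count_threshold(t_map: np.ndarray, mask: np.ndarray,
                          n: int) -> np.ndarray:
    """Mask of the n in-mask voxels with the largest t values.

    Ties at the cut are broken deterministically by lexicographic voxel
    index (C order).
    """
    mask = np.asarray(mask).astype(bool)
    n_mask = int(mask.sum())
    if n < 0 or n > n_mask:
        raise ValueError(f"n={n} outside [0, {n_mask}]")
    out = np.zeros(mask.shape, dtype=bool)
    if n == 0:
        return out
    flat_idx = np.flatnonzero(mask.ravel())
    vals = np.asarray(t_map).ravel()[flat_idx]
    order = np.argsort(-vals, kind="stable")
    out.ravel()[flat_idx[order[:n]]] = True
    return out


@dataclasses.dataclass
class SplitHalfResult:
    odd_reliability: ReliabilityMap
    even_reliability: ReliabilityMap
    odd_glm: GlmResult
    even_glm: GlmResult
    dice_table: pd.DataFrame
    congruence_unbiased: np.ndarray
    congruence_glm: np.ndarray
    display_threshold: float


def _congruence(odd_mask: np.ndarray, even_mask: np.ndarray) -> np.ndarray:
    lab = np.zeros(odd_mask.shape, dtype=np.int16)
    lab[odd_mask & even_mask] = CONGRUENCE_BOTH
    lab[odd_mask & ~even_mask] = CONGRUENCE_ODD
    lab[~odd_mask & even_mask] = CONGRUENCE_EVEN
    return lab


def split_half(session: Session, reliability_step: float = 5.0,
               display_threshold: float = 50.0, exclude_bad: bool = False,
               p_threshold: float = 0.001) -> SplitHalfResult:
    """Odd/even split-half congruence of both analysis methods.

    Runs are split by 1-based acquisition position (1,3,5,... vs 2,4,6,...).
    Within-half bad-run exclusion is off by default so both halves keep the
    matched pair count.  For each reliability threshold r the consistency
    masks are {reliability >= r} per half; the GLM masks select, per half,
    as many voxels (largest t) as that half's consistency mask contains.
    """
    if session.n_runs < 4:
        raise ValueError("split-half needs at least 4 runs")
    odd = session.subset(range(0, session.n_runs, 2))
    even = session.subset(range(1, session.n_runs, 2))

    halves = {}
    for name, half in (("odd", odd), ("even", even)):
        res = run_unbiased(half, detrend=True, exclude_bad=exclude_bad,
                           p_threshold=p_threshold)
        g = glm_session(res.session)
        halves[name] = (res.reliability, g)

    rel_o, glm_o = halves["odd"]
    rel_e, glm_e = halves["even"]
    mask = session.mask

    rows = []
    thresholds = np.arange(0.0, 100.0 + 1e-9, reliability_step)
    for thr in thresholds:
        m_o = (rel_o.values >= thr) & mask
        m_e = (rel_e.values >= thr) & mask
        n_o, n_e = int(m_o.sum()), int(m_e.sum())
        g_o = match_count_threshold(glm_o.t, mask, n_o)
        g_e = match_count_threshold(glm_e.t, mask, n_e)
        rows.append({
            "threshold_pct": thr,
            "dice_unbiased": dice(m_o, m_e),
            "dice_glm": dice(g_o, g_e),
            "n_voxels_odd": n_o,
            "n_voxels_even": n_e,
            "degenerate": n_o + n_e == 0,
        })
    table = pd.DataFrame(rows)

    m_o = (rel_o.values >= display_threshold) & mask
    m_e = (rel_e.values >= display_threshold) & mask
    g_o = match_count_threshold(glm_o.t, mask, int(m_o.sum()))
    g_e = match_count_threshold(glm_e.t, mask, int(m_e.sum()))
    return SplitHalfResult(odd_reliability=rel_o, even_reliability=rel_e,
                           odd_glm=glm_o, even_glm=glm_e, dice_table=table,
                           congruence_unbiased=_congruence(m_o, m_e),
                           congruence_glm=_congruence(g_o, g_e),
                           display_threshold=display_threshold)


def shift_sensitivity(session: Session, shifts_volumes: Sequence[int],
                      roi: np.ndarray,
                      good_runs: Iterable[int] | None = None,
                      p_threshold: float = 0.001,
                      detrend: bool = True) -> pd.DataFrame:
    """Re-analyse the session under global circular time shifts.

    Detrending is applied once, before shifting, so each shifted analysis
    sees the same samples in permuted order.  Returns one row per shift
    with the mean GLM t and the mean reliability inside the ROI.
    """
    roi = np.asarray(roi).astype(bool)
    base = detrend_session(session) if detrend else session
    good = list(good_runs) if good_runs is not None else list(range(session.n_runs))
    reg = block_regressor(session.design, session.n_volumes, session.tr)
    rows = []
    for s in shifts_volumes:
        shifted = shift_session(base, s) if s != 0 else base
        pairs = all_pair_fits(shifted)
        rel = reliability_map(pairs, good, p_threshold=p_threshold)
        g = glm_session(shifted, regressor=reg, good_runs=good)
        rows.append({
            "shift_seconds": s * session.tr,
            "shift_volumes": s,
            "mean_glm_t_in_roi": float(g.t[roi].mean()),
            "mean_reliability_in_roi": float(rel.values[roi].mean()),
        })
    return pd.DataFrame(rows)
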