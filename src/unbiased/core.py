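"""The UNBIASED method: inter-run regression, bad-run exclusion, reliability.

Instead of fitting a hemodynamic model, every voxel's "model" is its own
time course in another run of the same task.  For each unordered pair of
runs (j, k) the voxel time course of run k is regressed on that of run j
(with an intercept); the slope t statistic measures inter-run consistency.
Per voxel the N*(N-1)/2 pairwise t values support

* a subject-level one-sample t map over the pairwise slopes,
* an automatic exclusion of low-quality runs (one-sided Welch tests between
  t maps computed with and without each run, Bonferroni-corrected), and
* the final reliability map: the percentage of good-run pairs whose t value
  exceeds an uncorrected p < 0.001 threshold.

Because the inter-run slope is invariant to a common temporal permutation
and to a global sign flip of the data, the reliability map is insensitive
to consistent response delays, shape changes and deactivations.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, stats

from .data_io import RunSeries, Session

logger = logging.getLogger(__name__)

#: substitute t magnitude for degenerate zero-residual fits, keeping
#: downstream percentiles and Welch tests finite
T_CLAMP = 1.0e6

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class PairFit:
    """OLS fit of run k's voxel time courses on run j's (j < k)."""

    j: int
    k: int
    beta: np.ndarray   # 3D slope map, zero outside mask
    t: np.ndarray      # 3D t map (beta / SE), zero outside mask
    r2: np.ndarray     # 3D coefficient of determination of the pair fit
    ss_tot: np.ndarray  # 3D total sum of squares of the response run
    dof: int           # residual degrees of freedom, T - 2


@dataclasses.dataclass
class PairStatSet:
    """All N*(N-1)/2 pairwise fits of a session."""

    pairs: list[PairFit]
    n_runs: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        expect = self.n_runs * (self.n_runs - 1) // 2
        if len(self.pairs) != expect:
            raise ValueError(f"expected {expect} pairs, got {len(self.pairs)}")

    @property
    def dof(self) -> int:
        return self.pairs[0].dof

    def select(self, included_runs: Iterable[int]) -> list[PairFit]:
        inc = set(included_runs)
        return [p for p in self.pairs if p.j in inc and p.k in inc]


@dataclasses.dataclass
class PassRecord:
    """One Welch test performed during bad-run identification."""

    pass_index: int
    run_id: int
    welch_t: float
    welch_dof: float
    p_one_sided: float
    alpha_corrected: float
    decision: str  # "kept" | "flagged" | "excluded"


@dataclasses.dataclass
class BadRunReport:
    excluded: list[int]
    passes: list[PassRecord]
    activation_mask: np.ndarray | None
    good_runs: list[int]


@dataclasses.dataclass
class ReliabilityMap:
    """Per-voxel percentage of good-run pairs with supra-threshold t."""

    values: np.ndarray
    n_good_runs: int
    n_pairs: int
    t_threshold: float
    p_threshold: float


def _ols_slope(x: np.ndarray, y: np.ndarray):
    """Vectorised OLS of y on [1, x] along the last axis.

    Returns (beta, t, r2, ss_tot, dof).  Zero-variance predictor or
    response gives beta = t = 0; zero-residual (perfect) fits get t clamped
    to +-T_CLAMP.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    T = x.shape[-1]
    dof = T - 2
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = np.einsum("...t,...t->...", xc, xc)
    syy = np.einsum("...t,...t->...", yc, yc)
    sxy = np.einsum("...t,...t->...", xc, yc)
    ok = (sxx > 0) & (syy > 0)
    beta = np.where(ok, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    ss_res = np.maximum(syy - beta * sxy, 0.0)
    r2 = np.where(ok, 1.0 - ss_res / np.where(syy > 0, syy, 1.0), 0.0)
    perfect = ok & (ss_res <= syy * 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta * np.sqrt(dof * sxx / np.where(ss_res > 0, ss_res, np.nan))
    t = np.where(perfect, np.sign(beta) * T_CLAMP, t)
    t = np.where(ok, np.nan_to_num(t, nan=0.0, posinf=T_CLAMP, neginf=-T_CLAMP), 0.0)
    t = np.clip(t, -T_CLAMP, T_CLAMP)
    return beta, t, r2, np.where(ok, syy, 0.0), dof


def pair_fit(run_j: RunSeries, run_k: RunSeries, mask: np.ndarray) -> PairFit:
    """Regress run k's voxel time courses on run j's inside the mask."""
    if run_j.data.shape != run_k.data.shape:
        raise ValueError("runs must share the same grid and volume count")
    if run_j.run_id == run_k.run_id:
        raise ValueError("pair fits are defined for non-identical runs only")
    mask = np.asarray(mask).astype(bool)
    x = run_j.data[mask]
    y = run_k.data[mask]
    beta_v, t_v, r2_v, sst_v, dof = _ols_slope(x, y)
    shape = run_j.spatial_shape

    def _full(v):
        out = np.zeros(shape)
        out[mask] = v
        return out

    j, k = sorted((run_j.run_id, run_k.run_id))
    return PairFit(j=j, k=k, beta=_full(beta_v), t=_full(t_v),
                   r2=_full(r2_v), ss_tot=_full(sst_v), dof=dof)


def all_pair_fits(session: Session) -> PairStatSet:
    """Pairwise fits for every non-identical run combination j < k."""
    N = session.n_runs
    pairs = [pair_fit(session.runs[j], session.runs[k], session.mask)
             for j, k in itertools.combinations(range(N), 2)]
    return PairStatSet(pairs=pairs, n_runs=N, mask=session.mask.astype(bool))


def subject_t_map(pairs: PairStatSet, included_runs: Iterable[int]) -> np.ndarray:
    """One-sample t over the pairwise slopes of the included runs.

    Per masked voxel: t = mean(beta) * sqrt(P) / sd(beta) over the P pairs
    whose runs are both included.  A degenerate zero spread is clamped.
    """
    sel = pairs.select(included_runs)
    P = len(sel)
    if P < 2:
        raise ValueError("a one-sample t map requires at least 2 pairs")
    mask = pairs.mask
    b = np.stack([p.beta[mask] for p in sel])
    m = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m * np.sqrt(P) / sd
    t = np.where(sd > 0, t, np.where(m == 0.0, 0.0, np.sign(m) * T_CLAMP))
    t = np.clip(t, -T_CLAMP, T_CLAMP)
    out = np.zeros(mask.shape)
    out[mask] = t
    return out


def activation_mask(t_map: np.ndarray, brain_mask: np.ndarray,
                    top_percent: float = 1.0,
                    smooth_fwhm_vox: float = 2.0) -> np.ndarray:
    """Smoothed mask of the top-percentile t voxels.

    The strict top ``top_percent`` percent of in-mask t values are
    binarized, smoothed with a 3D Gaussian (FWHM in voxels) and
    re-binarized at > 0.5; smoothing removes isolated suprathreshold voxels
    while keeping contiguous activation foci.  If smoothing empties the
    mask the unsmoothed top-percentile set is returned instead.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    vals = np.asarray(t_map)[brain_mask]
    thr = np.quantile(vals, 1.0 - top_percent / 100.0)
    raw = (t_map > thr) & brain_mask
    if not raw.any():
        logger.info("activation mask: no strict supra-threshold voxel, "
                    "falling back to ties at the percentile cut")
        raw = (t_map >= thr) & brain_mask
    if smooth_fwhm_vox <= 0:
        return raw
    sm = ndimage.gaussian_filter(raw.astype(np.float64),
                                 sigma=smooth_fwhm_vox * _FWHM_TO_SIGMA)
    out = (sm > 0.5) & brain_mask
    if not out.any():
        logger.info("activation mask: smoothing emptied the mask, "
                    "using the unsmoothed top-percentile set")
        return raw
    return out


def welch_one_sided(sample_a: np.ndarray, sample_b: np.ndarray):
    """Welch's two-sample t test against the alternative mean_b > mean_a.

    Returns (t, Welch-Satterthwaite dof, one-sided p).  Identical constant
    samples yield (0, n_a + n_b - 2, 0.5).
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("both samples need at least 2 elements")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 0.5
    t = (b.mean() - a.mean()) / np.sqrt(se2)
    dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(stats.t.sf(t, dof))
    return float(t), float(dof), p


def _run_mean_t(pairs: PairStatSet, good: Sequence[int], run: int,
                act: np.ndarray) -> float:
    """Mean in-mask subject-level t over only the pairs involving ``run``."""
    sel = [p for p in pairs.select(good) if run in (p.j, p.k)]
    mask = pairs.mask
    b = np.stack([p.beta[mask] for p in sel])
    m = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m * np.sqrt(len(sel)) / sd
    t = np.where(sd > 0, t, np.where(m == 0.0, 0.0, np.sign(m) * T_CLAMP))
    full = np.zeros(mask.shape)
    full[mask] = np.clip(t, -T_CLAMP, T_CLAMP)
    return float(full[act].mean())


def detect_bad_runs(pairs: PairStatSet, alpha: float = 0.05,
                    top_percent: float = 1.0, smooth_fwhm_vox: float = 2.0,
                    selection: str = "run_mean_t") -> BadRunReport:
    """Iteratively exclude runs that depress the subject-level t map.

    Each pass computes the subject t map over the current good runs and an
    activation mask of its top-percentile voxels, then tests every candidate
    run n with a one-sided Welch test of whether the leave-n-out t map
    exceeds the all-runs t map inside the activation mask.  Rejection at the
    Bonferroni-corrected level (alpha / runs tested this pass) flags the
    run; among multiply-flagged runs exactly one is excluded per pass:

    * ``selection="run_mean_t"`` (default): the flagged run with the
      smallest mean in-mask t computed from only the pairs involving it;
    * ``selection="welch"``: the flagged run with the largest Welch t
      (whose removal improves the map the most).

    Passes repeat until no rejection, or until only two good runs would
    remain.  With fewer than three good runs no testing is possible.
    """
    if selection not in ("run_mean_t", "welch"):
        raise ValueError("selection must be 'run_mean_t' or 'welch'")
    N = pairs.n_runs
    good = list(range(N))
    excluded: list[int] = []
    records: list[PassRecord] = []
    act: np.ndarray | None = None

    if len(good) < 3:
        logger.info("bad-run detection skipped: fewer than 3 runs")
        return BadRunReport(excluded=[], passes=[], activation_mask=None,
                            good_runs=good)

    pass_index = 0
    while len(good) > 2:
        t_all = subject_t_map(pairs, good)
        act = activation_mask(t_all, pairs.mask, top_percent, smooth_fwhm_vox)
        sample_all = t_all[act]
        n_tested = len(good)
        alpha_corr = alpha / n_tested
        flagged: dict[int, float] = {}
        pass_records: list[PassRecord] = []
        for n in good:
            rest = [g for g in good if g != n]
            t_excl = subject_t_map(pairs, rest)
            tw, dof, p = welch_one_sided(sample_all, t_excl[act])
            decision = "flagged" if p < alpha_corr else "kept"
            pass_records.append(PassRecord(pass_index, n, tw, dof, p,
                                           alpha_corr, decision))
            if p < alpha_corr:
                flagged[n] = tw
        if not flagged:
            records.extend(pass_records)
            break
        if selection == "welch":
            worst = max(flagged, key=lambda n: flagged[n])
        else:
            scores = {n: _run_mean_t(pairs, good, n, act) for n in flagged}
            worst = min(scores, key=lambda n: scores[n])
        for rec in pass_records:
            if rec.run_id == worst:
                rec.decision = "excluded"
        records.extend(pass_records)
        good.remove(worst)
        excluded.append(worst)
        pass_index += 1

    return BadRunReport(excluded=excluded, passes=records,
                        activation_mask=act, good_runs=good)


def reliability_map(pairs: PairStatSet, good_runs: Iterable[int],
                    p_threshold: float = 0.001) -> ReliabilityMap:
    """Percentage of good-run pairs whose t exceeds the p < 0.001 cut.

    The threshold is the upper-tail Student-t quantile at ``p_threshold``
    with the pair fits' residual dof; only the positive tail is counted, so
    consistent responses of either BOLD sign score alike while anti-
    correlated behaviour does not.
    """
    sel = pairs.select(good_runs)
    if len(sel) < 1 or len({r for p in sel for r in (p.j, p.k)}) < 2:
        raise ValueError("reliability requires at least 2 good runs")
    thr = float(stats.t.isf(p_threshold, sel[0].dof))
    mask = pairs.mask
    counts = np.zeros(mask.sum(), dtype=np.int64)
    for p in sel:
        counts += p.t[mask] > thr
    values = np.zeros(mask.shape)
    values[mask] = 100.0 * counts / len(sel)
    good = sorted({r for p in sel for r in (p.j, p.k)})
    return ReliabilityMap(values=values, n_good_runs=len(good),
                          n_pairs=len(sel), t_threshold=thr,
                          p_threshold=p_threshold)


def mean_beta_map(pairs: PairStatSet, good_runs: Iterable[int]) -> np.ndarray:
    """Arithmetic mean of the pairwise slopes over good-run pairs.

    Useful for distinguishing true activation (slopes near 1) from
    artefacts when the number of runs, and hence reliability levels, is low.
    """
    sel = pairs.select(good_runs)
    if len({r for p in sel for r in (p.j, p.k)}) < 2:
        raise ValueError("mean beta requires at least 2 good runs")
    return np.mean([p.beta for p in sel], axis=0)
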