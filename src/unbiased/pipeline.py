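"""End-to-end convenience wrapper: detrend, pair fits, exclusion, maps."""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import (BadRunReport, PairStatSet, ReliabilityMap, all_pair_fits,
                   detect_bad_runs, mean_beta_map, reliability_map,
                   subject_t_map)
from .data_io import Session
from .preprocess import detrend_session


@dataclasses.dataclass
class UnbiasedResult:
    reliability: ReliabilityMap
    t_map: np.ndarray | None       # subject-level t over good pairs (P >= 2)
    mean_beta: np.ndarray
    report: BadRunReport
    pairs: PairStatSet
    session: Session               # the (detrended) session analysed


def run_unbiased(session: Session, detrend: bool = True,
                 exclude_bad: bool = True, p_threshold: float = 0.001,
                 alpha: float = 0.05, top_percent: float = 1.0,
                 smooth_fwhm_vox: float = 2.0,
                 selection: str = "run_mean_t") -> UnbiasedResult:
    """Run the full inter-run consistency analysis on a session."""
    if detrend:
        session = detrend_session(session)
    pairs = all_pair_fits(session)
    if exclude_bad:
        report = detect_bad_runs(pairs, alpha=alpha, top_percent=top_percent,
                                 smooth_fwhm_vox=smooth_fwhm_vox,
                                 selection=selection)
    else:
        report = BadRunReport(excluded=[], passes=[], activation_mask=None,
                              good_runs=list(range(session.n_runs)))
    good = report.good_runs
    rel = reliability_map(pairs, good, p_threshold=p_threshold)
    t_map = subject_t_map(pairs, good) if rel.n_pairs >= 2 else None
    beta = mean_beta_map(pairs, good)
    return UnbiasedResult(reliability=rel, t_map=t_map, mean_beta=beta,
                          report=report, pairs=pairs, session=session)
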