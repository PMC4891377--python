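"""Per-voxel baseline drift removal and circular temporal shifting.

Scanner drift is removed by subtracting, independently in each run, the
least-squares second-order polynomial fit to each voxel time series.  The
polynomial time variable is the volume index 0..T-1; the basis span (and
therefore the residual) is invariant to the choice of time units.
"""

from __future__ import annotations

import numpy as np

from .data_io import RunSeries, Session


def _poly_basis(n_volumes: int) -> np.ndarray:
    t = np.arange(n_volumes, dtype=np.float64)
    return np.column_stack([np.ones_like(t), t, t * t])


def detrend_poly2(run: RunSeries, mask: np.ndarray | None = None) -> RunSeries:
    """Subtract the best-fitting a0 + a1*t + a2*t^2 from each voxel.

    Voxels outside ``mask`` (when given) are zeroed.  The output is
    orthogonal to the polynomial basis, so the operation is idempotent and
    detrended voxel means are ~0.
    """
    T = run.n_volumes
    if T < 4:
        raise ValueError("detrending needs at least 4 volumes")
    X = _poly_basis(T)
    # hat-complement applied to the time axis: resid = Y - X (X^+ Y)
    pinv = np.linalg.pinv(X)
    flat = run.data.reshape(-1, T)
    if mask is not None:
        mask = np.asarray(mask).astype(bool).reshape(-1)
        sel = flat[mask]
        resid = np.zeros_like(flat)
        resid[mask] = sel - (X @ (pinv @ sel.T)).T
    else:
        resid = flat - (X @ (pinv @ flat.T)).T
    return run.copy_with(resid.reshape(run.data.shape))


def circular_shift(run: RunSeries, n_volumes: int) -> RunSeries:
    """Circularly shift the time axis by ``n_volumes``.

    Positive shifts move the final volumes to the beginning of the series
    (delaying the data relative to the task), negative shifts move the first
    volumes to the end.  A shift of 0 is the identity.
    """
    T = run.n_volumes
    if abs(int(n_volumes)) >= T:
        raise ValueError(f"|shift| must be smaller than the {T} volumes")
    return run.copy_with(np.roll(run.data, int(n_volumes), axis=3))


def detrend_session(session: Session) -> Session:
    """Detrend every run of a session inside its brain mask."""
    runs = [detrend_poly2(r, session.mask) for r in session.runs]
    return Session(runs=runs, mask=session.mask.copy(), design=session.design)


def shift_session(session: Session, n_volumes: int) -> Session:
    """Apply the same circular shift to every run of a session."""
    runs = [circular_shift(r, n_volumes) for r in session.runs]
    return Session(runs=runs, mask=session.mask.copy(), design=session.design)
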