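"""Temporal cleaning of ROI time series.

The cleaning pipeline mirrors standard resting-state practice at the
ROI level: (1) detrending and nuisance regression (Friston-24 motion
expansion plus white-matter and CSF signals), (2) motion scrubbing by
framewise displacement (FD) and DVARS, (3) band-pass filtering at
0.01-0.08 Hz with censored frames linearly interpolated before the
filter and re-censored afterwards. Downstream correlation estimation
uses valid frames only.

Spatial preprocessing (slice timing, realignment estimation,
normalization, smoothing) is out of scope: inputs are already
region-averaged signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .cohort import MotionTrace, RoiTimeSeriesSet

logger = logging.getLogger(__name__)

#: Radius (mm) of the sphere onto which rotational displacements are
#: projected when converting radians to millimetres.
HEAD_RADIUS_MM = 50.0


def compute_fd(params: np.ndarray) -> np.ndarray:
    """Framewise displacement (Power convention).

    FD(t) = sum of absolute frame-to-frame differences of the three
    translations (mm) plus the three rotations (radians) projected onto
    a 50 mm sphere. The first frame is 0 by convention.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"expected frames x 6 motion parameters, got {params.shape}")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(axis=1) + d[:, 3:].sum(axis=1) * HEAD_RADIUS_MM
    return np.concatenate([[0.0], fd])


def compute_dvars(data: np.ndarray) -> np.ndarray:
    """DVARS: root-mean-square across nodes of the frame-difference
    signal, expressed as a percentage of the grand mean signal. First
    frame 0 by convention."""
    data = np.asarray(data, dtype=float)
    grand_mean = float(np.abs(data).mean())
    if grand_mean <= 0:
        return np.zeros(data.shape[0])
    rms = np.sqrt((np.diff(data, axis=0) ** 2).mean(axis=1))
    return np.concatenate([[0.0], rms / grand_mean * 100.0])


@dataclass
class ScrubReport:
    n_scrubbed: int
    fraction: float
    flagged: bool  # True when more than `max_fraction` of frames were removed


def scrub(
    ts: RoiTimeSeriesSet,
    trace: MotionTrace,
    fd_thresh: float = 0.5,
    dvars_thresh: float = 0.5,
    rule: str = "and",
    max_fraction: float = 0.05,
) -> tuple[RoiTimeSeriesSet, ScrubReport]:
    """Invalidate motion-contaminated frames.

    A frame is scrubbed when FD > ``fd_thresh`` (mm) AND DVARS >
    ``dvars_thresh`` (%); ``rule="or"`` switches to the disjunction.
    Subjects losing more than ``max_fraction`` of their frames are
    flagged (and logged), not silently passed.
    """
    if trace.fd.shape[0] != ts.n_frames:
        raise ValueError("motion trace not aligned to time series frames")
    if rule == "and":
        bad = (trace.fd > fd_thresh) & (trace.dvars > dvars_thresh)
    elif rule == "or":
        bad = (trace.fd > fd_thresh) | (trace.dvars > dvars_thresh)
    else:
        raise ValueError("rule must be 'and' or 'or'")
    mask = ts.valid_mask & ~bad
    n_scrubbed = int((ts.valid_mask & bad).sum())
    fraction = n_scrubbed / ts.n_frames
    flagged = fraction > max_fraction
    if flagged:
        logger.warning(
            "subject %s: %.1f%% of frames scrubbed (> %.0f%% limit)",
            ts.subject_id,
            100 * fraction,
            100 * max_fraction,
        )
    return replace(ts, valid_mask=mask), ScrubReport(n_scrubbed, fraction, flagged)


def friston24(params: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion expansion: the six parameters, their
    squares, their one-frame lags, and the lagged squares."""
    p = np.asarray(params, dtype=float)
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, p**2, lag, lag**2])


def _drop_collinear(design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep a maximal linearly independent subset of columns (QR with
    column pivoting); returns (reduced design, kept column indices)."""
    from scipy.linalg import qr

    norms = np.linalg.norm(design, axis=0)
    norms[norms == 0] = 1.0
    _, r, piv = qr(design / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < design.shape[1]:
        logger.warning(
            "nuisance design rank-deficient: dropping %d collinear column(s)",
            design.shape[1] - rank,
        )
    return design[:, keep], keep


def nuisance_regress(
    ts: RoiTimeSeriesSet,
    trace: MotionTrace,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> RoiTimeSeriesSet:
    """Per-node OLS residualization against intercept, linear trend, the
    Friston-24 motion expansion, and WM/CSF signals.

    Residuals are exactly orthogonal (in sample) to every retained
    regressor. Collinear design columns are dropped with a warning.
    """
    n = ts.n_frames
    if trace.params.shape[0] != n:
        raise ValueError("motion trace not aligned to time series frames")
    cols = [np.ones(n), np.linspace(-1.0, 1.0, n), *friston24(trace.params).T]
    for sig, name in ((wm_signal, "wm"), (csf_signal, "csf")):
        if sig is not None:
            sig = np.asarray(sig, dtype=float)
            if sig.shape[0] != n:
                raise ValueError(f"{name} regressor not aligned to frames")
            cols.append(sig)
    design = np.column_stack(cols)
    design, _ = _drop_collinear(design)
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return replace(ts, data=resid)


def bandpass(
    ts: RoiTimeSeriesSet, low: float = 0.01, high: float = 0.08
) -> RoiTimeSeriesSet:
    """Band-pass filter by a hard spectral mask retaining [low, high] Hz.

    Invalid frames are linearly interpolated before filtering and
    re-invalidated afterwards, so censored data cannot leak ringing into
    valid frames while the spectrum stays well defined on a regular
    grid. The zero-frequency (mean) component is removed.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high > nyquist + 1e-12:
        raise ValueError(f"high={high} Hz exceeds Nyquist {nyquist:.4f} Hz")
    n = ts.n_frames
    freqs = np.fft.rfftfreq(n, d=ts.tr_seconds)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not keep.any():
        raise ValueError("empty pass band for this series length")
    data = ts.data
    if not ts.valid_mask.all():
        t = np.arange(n, dtype=float)
        good = ts.valid_mask
        data = np.empty_like(ts.data)
        for j in range(ts.n_nodes):
            data[:, j] = np.interp(t, t[good], ts.data[good, j])
    spec = np.fft.rfft(data, axis=0)
    spec[~keep] = 0.0
    filtered = np.fft.irfft(spec, n=n, axis=0)
    return replace(ts, data=filtered)


@dataclass
class QcReport:
    subject_id: str
    mean_fd: float
    max_fd: float
    n_scrubbed: int
    scrub_fraction: float
    flagged: bool

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_fd": self.mean_fd,
            "max_fd": self.max_fd,
            "n_scrubbed": self.n_scrubbed,
            "scrub_fraction": self.scrub_fraction,
            "flagged": self.flagged,
        }


def clean_pipeline(
    ts: RoiTimeSeriesSet,
    trace: MotionTrace,
    fd_thresh: float = 0.5,
    dvars_thresh: float = 0.5,
    scrub_rule: str = "and",
    low: float = 0.01,
    high: float = 0.08,
) -> tuple[RoiTimeSeriesSet, QcReport]:
    """Full temporal cleaning for one subject.

    Order: detrend + nuisance regression, scrub flagging, interpolation
    and band-pass filtering, re-censoring.
    """
    resid = nuisance_regress(ts, trace, ts.wm, ts.csf)
    scrubbed, report = scrub(
        resid, trace, fd_thresh=fd_thresh, dvars_thresh=dvars_thresh, rule=scrub_rule
    )
    filtered = bandpass(scrubbed, low=low, high=high)
    qc = QcReport(
        subject_id=ts.subject_id,
        mean_fd=float(trace.fd.mean()),
        max_fd=float(trace.fd.max()),
        n_scrubbed=report.n_scrubbed,
        scrub_fraction=report.fraction,
        flagged=report.flagged,
    )
    return filtered, qc
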