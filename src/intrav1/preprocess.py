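"""Single-subject fMRI preprocessing.

The pipeline for one run is: nuisance regression (supplied confounds plus a
discrete-cosine drift basis implementing the 128 s high-pass, plus an
intercept), optionally a deconvolution GLM that removes the stimulus-evoked
response (canonical-HRF boxcar regressors, or a flexible FIR basis of 19
unit-amplitude sticks per condition), and finally segmentation of the
lag-shifted 20 s stimulation windows, linear detrending of each segment,
and concatenation of same-condition segments across runs.

Deconvolution always operates on whole runs, before segmentation and
detrending; the two orders are not equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .design import CONDITIONS, STIM_S, BlockSchedule

#: canonical double-gamma parameters (peak delay 6 s, undershoot delay 16 s,
#: dispersions 1 s, peak:undershoot ratio 6, kernel length 32 s)
HRF_PEAK_DELAY = 6.0
HRF_UNDER_DELAY = 16.0
HRF_RATIO = 6.0
HRF_LENGTH_S = 32.0

FIR_N_BASIS = 19
DEFAULT_LAG_S = 5.0
DEFAULT_HIGHPASS_S = 128.0


@dataclass(frozen=True)
class HRFKernel:
    kind: str  # 'canonical' or 'FIR'
    tr: float
    samples: np.ndarray | None = None
    n_basis: int | None = None


@dataclass
class ConditionSeries:
    """Concatenated, detrended stimulation-epoch time series of one condition."""

    subject_id: str
    condition: str
    scheme: str
    data: np.ndarray  # time x vertex
    segment_boundaries: np.ndarray  # start index of each segment

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


def hrf_curve(t: np.ndarray) -> np.ndarray:
    """Continuous-time canonical HRF evaluated at times t (seconds)."""
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, a=HRF_PEAK_DELAY, scale=1.0)
    under = stats.gamma.pdf(t, a=HRF_UNDER_DELAY, scale=1.0)
    return peak - under / HRF_RATIO


def canonical_hrf(tr: float) -> HRFKernel:
    """Canonical double-gamma HRF sampled on the TR grid over 32 s."""
    if tr <= 0:
        raise ValueError("TR must be positive")
    n = int(np.floor(HRF_LENGTH_S / tr)) + 1
    t = np.arange(n) * tr
    h = hrf_curve(t)
    h = h / h.sum()
    return HRFKernel(kind="canonical", tr=tr, samples=h)


def dct_drift_basis(n: int, tr: float, cutoff_s: float = DEFAULT_HIGHPASS_S) -> np.ndarray:
    """Discrete-cosine drift regressors with periods above ``cutoff_s``."""
    order = int(np.floor(2.0 * n * tr / cutoff_s))
    t = np.arange(n)
    basis = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n)) for k in range(1, order + 1)]
    if not basis:
        return np.empty((n, 0))
    return np.column_stack(basis)


def _ols_residuals(bold: np.ndarray, design: np.ndarray) -> np.ndarray:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient design matrix; using the pseudoinverse", stacklevel=3
        )
    beta = np.linalg.pinv(design) @ bold
    return bold - design @ beta


def nuisance_regress(
    bold: np.ndarray,
    confounds: np.ndarray | None,
    tr: float,
    highpass_cutoff_s: float = DEFAULT_HIGHPASS_S,
) -> np.ndarray:
    """Regress out confounds, drift and the mean; return the residuals."""
    n = bold.shape[0]
    if confounds is None:
        confounds = np.empty((n, 0))
    if confounds.shape[0] != n:
        raise ValueError("confounds and bold disagree on the time dimension")
    design = np.column_stack(
        [np.ones(n), confounds, dct_drift_basis(n, tr, highpass_cutoff_s)]
    )
    return _ols_residuals(bold, design)


def boxcar_regressor(
    onsets_s: list[float], duration_s: float, n: int, tr: float
) -> np.ndarray:
    """Stimulation boxcar on the TR grid (fractional bin overlap)."""
    edges = np.arange(n + 1) * tr
    box = np.zeros(n)
    for onset in onsets_s:
        lo = np.clip(edges[:-1], onset, onset + duration_s)
        hi = np.clip(edges[1:], onset, onset + duration_s)
        box += (hi - lo) / tr
    return box


def evoked_regressor(
    onsets_s: list[float], duration_s: float, n: int, tr: float
) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, truncated to the run."""
    box = boxcar_regressor(onsets_s, duration_s, n, tr)
    h = canonical_hrf(tr).samples
    return np.convolve(box, h)[:n]


def _condition_onsets(schedule: BlockSchedule, run: int, condition: str) -> list[float]:
    return [b.stim_onset_s for b in schedule.blocks_of(run, condition)]


def hrfc_design(schedule: BlockSchedule, run: int, n: int, tr: float) -> np.ndarray:
    """One canonical-HRF regressor per condition, plus intercept."""
    cols = [
        evoked_regressor(_condition_onsets(schedule, run, c), STIM_S, n, tr)
        for c in CONDITIONS
    ]
    return np.column_stack([np.ones(n), *cols])


def fir_design(
    schedule: BlockSchedule,
    run: int,
    n: int,
    tr: float,
    n_basis: int = FIR_N_BASIS,
) -> np.ndarray:
    """FIR stick basis: ``n_basis`` unit columns per condition.

    Sticks are anchored at each block's stimulation onset (nearest TR) and
    span lags 0 .. n_basis-1 TRs, covering the stimulation epoch plus the
    hemodynamic tail.
    """
    cols = np.zeros((n, len(CONDITIONS) * n_basis))
    for ci, cond in enumerate(CONDITIONS):
        for onset in _condition_onsets(schedule, run, cond):
            start = int(round(onset / tr))
            for lag in range(n_basis):
                idx = start + lag
                if idx < n:
                    cols[idx, ci * n_basis + lag] = 1.0
    return np.column_stack([np.ones(n), cols])


def deconvolve_glm(
    bold: np.ndarray,
    schedule: BlockSchedule,
    run: int,
    basis: str,
    tr: float | None = None,
) -> np.ndarray:
    """Remove the modeled stimulus-evoked response; return GLM residuals."""
    tr = schedule.tr if tr is None else tr
    n = bold.shape[0]
    if basis == "canonical":
        design = hrfc_design(schedule, run, n, tr)
    elif basis in ("FIR", "fir"):
        design = fir_design(schedule, run, n, tr)
        # near-duplicate stick columns arise when blocks of one condition
        # overlap on the TR grid
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn("collinear FIR design (overlapping windows)", stacklevel=2)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return _ols_residuals(bold, design)


def segment_concatenate(
    run_bolds: list[np.ndarray],
    schedule: BlockSchedule,
    condition: str,
    lag_s: float = DEFAULT_LAG_S,
    subject_id: str = "",
    scheme: str = "raw",
) -> ConditionSeries:
    """Extract, detrend and concatenate the lag-shifted stimulation windows.

    Each 20 s window yields ``STIM_S / TR`` = 8 samples; window starts are
    rounded to the nearest TR because the 44 s block length is not a
    multiple of the TR.
    """
    tr = schedule.tr
    n_win = int(round(STIM_S / tr))
    segments = []
    boundaries = []
    offset = 0
    for run, bold in enumerate(run_bolds):
        for block in schedule.blocks_of(run, condition):
            start = int(round((block.stim_onset_s + lag_s) / tr))
            if start + n_win > bold.shape[0]:
                raise ValueError(
                    f"stimulation window exceeds run length (run {run}, "
                    f"onset {block.stim_onset_s} s, lag {lag_s} s)"
                )
            seg = signal.detrend(bold[start : start + n_win], axis=0, type="linear")
            segments.append(seg)
            boundaries.append(offset)
            offset += n_win
    return ConditionSeries(
        subject_id=subject_id,
        condition=condition,
        scheme=scheme,
        data=np.concatenate(segments, axis=0),
        segment_boundaries=np.asarray(boundaries),
    )
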