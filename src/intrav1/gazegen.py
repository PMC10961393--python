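"""Synthetic gaze trajectories for the 20 s stimulation blocks.

A parametric stand-in for eye-tracker recordings: fixation centers scatter
around the lit-pixel centroid of the displayed stimulus with Gaussian
dispersion, durations are log-normal, and the trajectory is truncated so the
total dwell time never exceeds the stimulation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import NavonStimulus, place_on_screen

STIM_EPOCH_MS = 20_000.0
DEFAULT_SCREEN = (1280, 1024)


@dataclass(frozen=True)
class GazeTrajectory:
    """Ordered fixations on the screen (pixel coordinates, ms timing)."""

    x_px: np.ndarray
    y_px: np.ndarray
    duration_ms: np.ndarray
    onset_ms: np.ndarray
    screen: tuple[int, int]
    dva_per_pixel: float

    def __post_init__(self) -> None:
        if np.any(self.duration_ms <= 0):
            raise ValueError("fixation durations must be positive")
        w, h = self.screen
        if np.any((self.x_px < 0) | (self.x_px >= w) | (self.y_px < 0) | (self.y_px >= h)):
            raise ValueError("fixations must lie on the screen")
        if self.duration_ms.sum() > STIM_EPOCH_MS + 1e-9:
            raise ValueError("total dwell time exceeds the stimulation epoch")

    @property
    def n_fixations(self) -> int:
        return self.x_px.size

    @property
    def total_duration_ms(self) -> float:
        return float(self.duration_ms.sum())


def _screen_image(
    stimulus: NavonStimulus | np.ndarray, screen: tuple[int, int], scale: int
) -> np.ndarray:
    if isinstance(stimulus, NavonStimulus):
        return place_on_screen(stimulus, screen, scale=scale)
    image = np.asarray(stimulus, dtype=float)
    if image.shape != (screen[1], screen[0]):
        raise ValueError("raster does not match the screen geometry")
    return image


def simulate_gaze(
    stimulus: NavonStimulus | np.ndarray,
    n_fixations: int,
    dispersion_px: float,
    seed: int = 0,
    screen: tuple[int, int] = DEFAULT_SCREEN,
    scale: int = 1,
    mean_duration_ms: float = 300.0,
    duration_sigma: float = 0.5,
    dva_per_pixel: float = 0.01,
) -> GazeTrajectory:
    """Draw one fixation sequence for a displayed stimulus.

    ``dispersion_px = 0`` degenerates to every fixation at the lit-pixel
    centroid.  The last fixation is truncated (and later ones dropped) so
    the total duration stays within the 20 s stimulation epoch.
    """
    if n_fixations < 1:
        raise ValueError("need at least one fixation")
    if dispersion_px < 0:
        raise ValueError("dispersion must be non-negative")
    image = _screen_image(stimulus, screen, scale)
    rows, cols = np.nonzero(image)
    if rows.size == 0:
        raise ValueError("stimulus raster has no lit pixels")
    rng = np.random.default_rng(seed)
    cy, cx = rows.mean(), cols.mean()
    w, h = screen

    x = cx + dispersion_px * rng.standard_normal(n_fixations)
    y = cy + dispersion_px * rng.standard_normal(n_fixations)
    x = np.clip(x, 0, w - 1)
    y = np.clip(y, 0, h - 1)
    durations = rng.lognormal(np.log(mean_duration_ms), duration_sigma, n_fixations)

    ends = np.cumsum(durations)
    keep = int(np.searchsorted(ends, STIM_EPOCH_MS, side="left")) + 1
    keep = min(keep, n_fixations)
    durations = durations[:keep].copy()
    budget = STIM_EPOCH_MS - (ends[keep - 2] if keep > 1 else 0.0)
    durations[-1] = min(durations[-1], budget)
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return GazeTrajectory(
        x_px=x[:keep],
        y_px=y[:keep],
        duration_ms=durations,
        onset_ms=onsets,
        screen=screen,
        dva_per_pixel=dva_per_pixel,
    )
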