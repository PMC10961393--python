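"""Gabor-pyramid simulation of gaze effects on V1-like fMRI.

V1 is modeled as a pyramid of quadrature Gabor filters: five spatial
frequencies (1, 2, 4, 8 and 16 cycles/FOV), eight orientations and two
phases, tiled over the screen at 2, 8, 16, 64 and 256 evenly spaced
positions per level (346 positions in total).  For every fixation the
stimulus is re-centered on the retina (translated opposite to the gaze
offset), filtered, and collapsed to one value per position by quadrature
energy over phases summed over orientations.  The per-fixation responses
are expanded in time by fixation duration on a 1 ms grid, convolved with
the canonical HRF, and sampled at the fMRI TR; no noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .gazegen import GazeTrajectory
from .preprocess import hrf_curve

DEFAULT_LEVELS = (1, 2, 4, 8, 16)
#: evenly spaced tiling per level: (nx, ny) grid, nx*ny positions
LEVEL_GRIDS = {1: (2, 1), 2: (4, 2), 4: (4, 4), 8: (8, 8), 16: (16, 16)}
N_ORIENTATIONS = 8
DT_MS = 1.0
BLOCK_MS = 20_000.0


@dataclass
class LevelBank:
    cycles_per_fov: int
    centers: np.ndarray  # n_positions x 2, (x, y) px
    kernels: np.ndarray  # (n_orient * 2) x kh x kw, even phase then odd
    half: int  # kernel half width


@dataclass
class GaborBank:
    fov: tuple[int, int]  # (width, height) px
    levels: list[LevelBank]

    @property
    def n_nodes(self) -> int:
        return sum(lb.centers.shape[0] for lb in self.levels)

    @property
    def n_filters(self) -> int:
        return self.n_nodes * N_ORIENTATIONS * 2

    @property
    def node_index(self) -> list[tuple[int, int]]:
        return [
            (lb.cycles_per_fov, p)
            for lb in self.levels
            for p in range(lb.centers.shape[0])
        ]


def _gabor_kernels(wavelength: float, half: int) -> np.ndarray:
    """Quadrature-pair kernels for all orientations, zero-mean enforced."""
    coords = np.arange(-half, half + 1)
    xg, yg = np.meshgrid(coords, coords)
    sigma = 0.5 * wavelength
    envelope = np.exp(-(xg**2 + yg**2) / (2.0 * sigma**2))
    kernels = []
    for k in range(N_ORIENTATIONS):
        theta = np.pi * k / N_ORIENTATIONS
        xr = xg * np.cos(theta) + yg * np.sin(theta)
        even = envelope * np.cos(2.0 * np.pi * xr / wavelength)
        even -= envelope * even.sum() / envelope.sum()  # kill the DC response
        odd = envelope * np.sin(2.0 * np.pi * xr / wavelength)
        kernels.extend([even, odd])
    return np.stack(kernels)


def build_gabor_bank(
    fov_px: tuple[int, int] = (1280, 1024),
    levels: tuple[int, ...] = DEFAULT_LEVELS,
) -> GaborBank:
    """Construct the filter pyramid for a given field of view."""
    width, height = fov_px
    if width < 64 or height < 64:
        raise ValueError("field of view must be at least 64 px in each dimension")
    banks = []
    for cycles in levels:
        nx, ny = LEVEL_GRIDS[cycles]
        wavelength = width / cycles
        # support of ~2 sigma, truncated so coarse kernels still fit the FOV
        half = min(int(np.ceil(wavelength)), (min(width, height) - 1) // 2)
        if half < 1:
            raise ValueError(
                f"Gabor kernel at {cycles} cycles/FOV exceeds the field of view"
            )
        xs = (np.arange(nx) + 0.5) * width / nx
        ys = (np.arange(ny) + 0.5) * height / ny
        cx, cy = np.meshgrid(xs, ys)
        centers = np.column_stack([cx.ravel(), cy.ravel()])
        banks.append(
            LevelBank(
                cycles_per_fov=cycles,
                centers=centers,
                kernels=_gabor_kernels(wavelength, half),
                half=half,
            )
        )
    return GaborBank(fov=fov_px, levels=banks)


def gaze_shift_stimulus(
    image: np.ndarray, fixation_xy: tuple[float, float]
) -> np.ndarray:
    """Retina-centered view: the screen image translated so that the
    fixated point lands at the screen center (zero-padded)."""
    h, w = image.shape
    dx = int(round(w / 2.0 - fixation_xy[0]))
    dy = int(round(h / 2.0 - fixation_xy[1]))
    out = np.zeros_like(image)
    src_r = slice(max(0, -dy), min(h, h - dy))
    dst_r = slice(max(0, dy), min(h, h + dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


def _patch(image: np.ndarray, cx: float, cy: float, half: int) -> np.ndarray:
    """Zero-padded square patch centered at (cx, cy)."""
    h, w = image.shape
    size = 2 * half + 1
    r0, c0 = int(round(cy)) - half, int(round(cx)) - half
    patch = np.zeros((size, size))
    rs, re = max(0, r0), min(h, r0 + size)
    cs, ce = max(0, c0), min(w, c0 + size)
    if rs < re and cs < ce:
        patch[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    return patch


def node_responses(bank: GaborBank, image: np.ndarray) -> np.ndarray:
    """One response per (level, position): quadrature energy over phases,
    summed over orientations.

    The image mean is removed first, so a uniform (DC) image drives no
    filter even where kernels are truncated by the screen border, and
    responses are invariant to contrast polarity inversion.
    """
    image = image - image.mean()
    out = []
    for lb in bank.levels:
        flat_kernels = lb.kernels.reshape(lb.kernels.shape[0], -1)
        patches = np.stack(
            [_patch(image, cx, cy, lb.half).ravel() for cx, cy in lb.centers]
        )
        resp = patches @ flat_kernels.T  # positions x (orient*2)
        resp = resp.reshape(len(lb.centers), N_ORIENTATIONS, 2)
        energy = np.hypot(resp[..., 0], resp[..., 1]).sum(axis=1)
        out.append(energy)
    return np.concatenate(out)


def fixation_node_responses(
    bank: GaborBank, image: np.ndarray, trajectory: GazeTrajectory
) -> np.ndarray:
    """Collapsed node responses for every fixation (n_fixations x n_nodes)."""
    if trajectory.n_fixations == 0:
        raise ValueError("empty trajectory")
    return np.stack(
        [
            node_responses(bank, gaze_shift_stimulus(image, (x, y)))
            for x, y in zip(trajectory.x_px, trajectory.y_px)
        ]
    )


@dataclass
class SimTimeSeries:
    responses: np.ndarray  # n_nodes x n_tr
    node_index: list[tuple[int, int]]
    subject_id: str = ""
    condition: str = ""


_HRF_CUMSUM: np.ndarray | None = None


def _hrf_cumulative() -> np.ndarray:
    """Integral of the unit-area canonical HRF on the 1 ms grid."""
    global _HRF_CUMSUM
    if _HRF_CUMSUM is None:
        t = np.arange(0.0, 32.0, DT_MS / 1000.0)
        h = hrf_curve(t)
        _HRF_CUMSUM = np.concatenate([[0.0], np.cumsum(h / h.sum())])
    return _HRF_CUMSUM


def _step_response(times_ms: np.ndarray) -> np.ndarray:
    """Response of the canonical HRF to a unit step, at times_ms.

    Matches the discrete convolution of the 1 ms sampled kernel with a unit
    step: out[t] = sum_{j<=t} h[j].
    """
    c = _hrf_cumulative()
    idx = np.clip(np.round(times_ms / DT_MS).astype(int) + 1, 0, c.size - 1)
    return np.where(times_ms < 0, 0.0, c[idx])


def simulate_bold(
    per_fixation: np.ndarray,
    trajectory: GazeTrajectory,
    tr: float = 2.5,
    block_ms: float = BLOCK_MS,
    node_index: list[tuple[int, int]] | None = None,
) -> SimTimeSeries:
    """Noise-free BOLD: fixation responses held for their durations on a
    1 ms grid, convolved with the canonical HRF, sampled at the TR grid.

    Because the input is piecewise constant, the convolution is evaluated
    exactly (at 1 ms resolution) from the HRF's cumulative step response,
    without materializing the millisecond series.
    """
    if per_fixation.shape[0] != trajectory.n_fixations:
        raise ValueError("one response vector per fixation required")
    if trajectory.n_fixations == 0:
        raise ValueError("empty trajectory")
    n_tr = int(round(block_ms / 1000.0 / tr))
    marks = np.arange(n_tr) * tr * 1000.0
    onsets = trajectory.onset_ms
    ends = np.minimum(onsets + trajectory.duration_ms, block_ms)
    # weight[k, f]: step response entering at onset_f minus leaving at end_f
    weight = _step_response(marks[:, None] - onsets[None, :]) - _step_response(
        marks[:, None] - ends[None, :]
    )
    return SimTimeSeries(
        responses=(weight @ per_fixation).T,
        node_index=node_index or [],
    )
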