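"""Fixation-duration heatmaps and mass-univariate cluster-mass inference.

Fixations are projected onto the screen as Dirac deltas weighted by their
durations, smoothed with a 2D Gaussian, and downsized by a factor 0.25.
Each pixel of the trial-wise heatmap stack is modeled with the linear mixed
model

    Fix_xy ~ 1 + Level + Letter + TrialOrder + Level:Letter + (1 | participant)

fit by maximum likelihood.  Family-wise inference uses a cluster-mass
statistic: parametric p-maps are thresholded at alpha / n_nonzero_pixels,
supra-threshold pixels form 8-connected clusters whose mass is the sum of
the tested contrast's coefficients, and significance comes from the maximum
cluster mass over participant bootstrap resamples of null-centered data.

The per-pixel fit is a vectorized profile-ML solver for the single
random-intercept model: the variance ratio theta = sigma_b^2 / sigma_e^2 is
profiled per pixel (all pixels share the grouping structure, so the
generalized-least-squares algebra vectorizes across pixels), which makes
whole-map refits cheap enough for bootstrap resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

DOWNSCALE = 0.25
KNOWN_KERNELS = (5.0, 10.0, 20.0, 40.0)
EFFECTS = ("Intercept", "Level", "Letter", "TrialOrder", "Level:Letter")


@dataclass
class Heatmap:
    grid: np.ndarray  # downsized screen, rows x cols
    kernel_sd: float
    participant: str = ""
    level: str = ""
    letter: str = ""
    trial_order: int = 0


@dataclass
class PixelModelMaps:
    coef: dict[str, np.ndarray]
    se: dict[str, np.ndarray]
    z: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    theta: np.ndarray
    mask: np.ndarray  # pixels with nonzero signal


@dataclass
class Cluster:
    pixels: np.ndarray  # boolean map
    mass: float
    p_boot: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    kernel_sd: float | None
    null_max_mass: np.ndarray


def fixation_heatmap(
    trajectory,
    kernel_sd: float,
    downscale: float = DOWNSCALE,
    **meta,
) -> Heatmap:
    """Duration-weighted fixation map, Gaussian-smoothed, block-downsized.

    The Gaussian kernel is normalized, so away from the borders the grid
    sums to the total fixation duration.
    """
    if kernel_sd not in KNOWN_KERNELS:
        warnings.warn(f"unusual kernel sd {kernel_sd} px", stacklevel=2)
    w, h = trajectory.screen
    impulse = np.zeros((h, w))
    for x, y, dur in zip(trajectory.x_px, trajectory.y_px, trajectory.duration_ms):
        r, c = int(round(y)), int(round(x))
        if not (0 <= r < h and 0 <= c < w):
            warnings.warn("fixation off screen; clipped", stacklevel=2)
            r, c = np.clip(r, 0, h - 1), np.clip(c, 0, w - 1)
        impulse[r, c] += dur
    if kernel_sd > 0:
        smooth = ndimage.gaussian_filter(impulse, kernel_sd, mode="constant")
    else:
        smooth = impulse
    factor = int(round(1.0 / downscale))
    hh, ww = (h // factor) * factor, (w // factor) * factor
    grid = (
        smooth[:hh, :ww]
        .reshape(hh // factor, factor, ww // factor, factor)
        .sum(axis=(1, 3))
    )
    return Heatmap(grid=grid, kernel_sd=kernel_sd, **meta)


def design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect design (effect coding) and participant group codes."""
    level = np.where(design["level"].to_numpy() == "Local", 0.5, -0.5)
    letter = np.where(design["letter"].to_numpy() == "U", 0.5, -0.5)
    order = design["trial_order"].to_numpy(dtype=float)
    order = order - order.mean()
    X = np.column_stack([np.ones(len(design)), level, letter, order, level * letter])
    groups = pd.factorize(design["participant"])[0]
    return X, groups


def _profile_stats(
    Y: np.ndarray, X: np.ndarray, groups: np.ndarray, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Negative profiled -2 log-likelihood and GLS pieces for per-pixel theta.

    Returns (-2ll per pixel, beta (k x P), xtvx (P x k x k), sigma2 (P,)).
    """
    n, k = X.shape
    n_groups = groups.max() + 1
    sizes = np.bincount(groups, minlength=n_groups).astype(float)
    # per-group sums
    Sx = np.zeros((n_groups, k))
    np.add.at(Sx, groups, X)
    Sy = np.zeros((n_groups, Y.shape[1]))
    np.add.at(Sy, groups, Y)
    # c[g, p] = theta_p / (1 + theta_p * n_g)
    c = theta[None, :] / (1.0 + np.outer(sizes, theta))
    xtx = X.T @ X
    xty = X.T @ Y
    yty = np.einsum("np,np->p", Y, Y)
    outer_x = np.einsum("gi,gj->gij", Sx, Sx)
    xtvx = xtx[None] - np.einsum("gp,gij->pij", c, outer_x)
    xtvy = xty - np.einsum("gp,gi,gp->ip", c, Sx, Sy)
    ytvy = yty - np.einsum("gp,gp,gp->p", c, Sy, Sy)
    beta = np.linalg.solve(xtvx, xtvy.T[..., None])[..., 0].T  # k x P
    rss = np.maximum(ytvy - np.einsum("ip,ip->p", beta, xtvy), 1e-300)
    sigma2 = rss / n
    logdet = np.log1p(np.outer(sizes, theta)).sum(axis=0)
    neg2ll = n * np.log(sigma2) + logdet + n * (1.0 + np.log(2.0 * np.pi))
    return neg2ll, beta, xtvx, sigma2


def _fit_random_intercept_ml(
    Y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Profile-ML fit of y = X b + (1|group) + e, vectorized over columns.

    Returns (beta k x P, se k x P, sigma2 P, theta P).
    """
    n, k = X.shape
    P = Y.shape[1]
    grid = np.concatenate([[0.0], np.logspace(-4, 3, 22)])
    scores = np.empty((grid.size, P))
    for gi, th in enumerate(grid):
        scores[gi] = _profile_stats(Y, X, groups, np.full(P, th))[0]
    best = scores.argmin(axis=0)
    # golden-section refinement on log-theta around the grid optimum
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid.size - 1)]
    lo = np.maximum(lo, 1e-6)
    hi = np.maximum(hi, 2e-6)
    for _ in range(20):
        m1 = np.exp(np.log(lo) + 0.382 * (np.log(hi) - np.log(lo)))
        m2 = np.exp(np.log(lo) + 0.618 * (np.log(hi) - np.log(lo)))
        f1 = _profile_stats(Y, X, groups, m1)[0]
        f2 = _profile_stats(Y, X, groups, m2)[0]
        take = f1 < f2
        hi = np.where(take, m2, hi)
        lo = np.where(take, lo, m1)
    theta = np.sqrt(lo * hi)
    # boundary check: theta = 0 (pure OLS) may beat the interior optimum
    f_theta = _profile_stats(Y, X, groups, theta)[0]
    f_zero = _profile_stats(Y, X, groups, np.zeros(P))[0]
    theta = np.where(f_zero <= f_theta, 0.0, theta)
    _, beta, xtvx, sigma2 = _profile_stats(Y, X, groups, theta)
    cov = np.linalg.inv(xtvx) * sigma2[:, None, None]
    se = np.sqrt(np.einsum("pii->ip", cov))
    return beta, se, sigma2, theta


def fit_pixel_models(
    stack: np.ndarray, design: pd.DataFrame
) -> PixelModelMaps:
    """Per-pixel random-intercept LMM (ML) over a heatmap stack.

    ``stack`` is (n_trials, rows, cols); ``design`` carries columns
    participant, level, letter, trial_order.  Pixels with no signal in any
    trial are masked out.  Wald z statistics and normal p-values are
    reported for each fixed effect.
    """
    if design["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    n_trials, rows, cols = stack.shape
    if len(design) != n_trials:
        raise ValueError("design rows must match the heatmap stack")
    X, groups = design_matrix(design)
    flat = stack.reshape(n_trials, rows * cols)
    mask_flat = np.any(flat != 0, axis=0)
    Y = flat[:, mask_flat]
    beta, se, sigma2, theta = _fit_random_intercept_ml(Y, X, groups)
    z = beta / se

    def unflatten(values: np.ndarray) -> np.ndarray:
        out = np.zeros(rows * cols)
        out[mask_flat] = values
        return out.reshape(rows, cols)

    coef, ses, zs, ps = {}, {}, {}, {}
    for i, name in enumerate(EFFECTS):
        coef[name] = unflatten(beta[i])
        ses[name] = unflatten(se[i])
        zs[name] = unflatten(z[i])
        pvals = 2.0 * stats.norm.sf(np.abs(z[i]))
        full = np.ones(rows * cols)
        full[mask_flat] = pvals
        ps[name] = full.reshape(rows, cols)
    return PixelModelMaps(
        coef=coef,
        se=ses,
        z=zs,
        p=ps,
        theta=unflatten(theta),
        mask=mask_flat.reshape(rows, cols),
    )


_STRUCTURE_8 = np.ones((3, 3), dtype=int)


def _clusters(
    p_map: np.ndarray, coef_map: np.ndarray, mask: np.ndarray, threshold: float
) -> list[tuple[np.ndarray, float]]:
    supra = (p_map < threshold) & mask
    labeled, n = ndimage.label(supra, structure=_STRUCTURE_8)
    out = []
    for lab in range(1, n + 1):
        pix = labeled == lab
        out.append((pix, float(coef_map[pix].sum())))
    return out


def cluster_mass_bootstrap(
    maps: PixelModelMaps,
    stack: np.ndarray,
    design: pd.DataFrame,
    effect: str = "Level",
    alpha_forming: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-mass family-wise inference via participant bootstrap.

    Original parametric p-maps are thresholded at
    ``alpha_forming / n_nonzero_pixels``; each 8-connected cluster's mass is
    the sum of the effect's coefficients within it.  The null distribution
    is the maximum |mass| over bootstrap resamples (participants with
    replacement) of data whose fitted effect contribution was removed.
    """
    if not 0 < alpha_forming < 1:
        raise ValueError("alpha_forming must lie in (0, 1)")
    n_nonzero = int(maps.mask.sum())
    if n_nonzero == 0:
        return ClusterResult([], np.nan, None, np.empty(0))
    threshold = alpha_forming / n_nonzero
    observed = _clusters(maps.p[effect], maps.coef[effect], maps.mask, threshold)
    if not observed:
        return ClusterResult([], threshold, None, np.empty(0))

    n_trials, rows, cols = stack.shape
    X, groups = design_matrix(design)
    eff_idx = EFFECTS.index(effect)
    # null-center: remove the fitted contribution of the tested effect
    null_stack = stack - np.einsum(
        "n,rc->nrc", X[:, eff_idx], maps.coef[effect]
    )
    rng = np.random.default_rng(seed)
    participants = np.unique(groups)
    rows_of = {g: np.flatnonzero(groups == g) for g in participants}
    blocks = [X[rows_of[g]] for g in participants]
    balanced = all(
        b.shape == blocks[0].shape and np.allclose(b, blocks[0]) for b in blocks
    )
    null_flat = null_stack.reshape(n_trials, rows * cols)[:, maps.mask.ravel()]
    null_max = np.empty(n_boot)
    if balanced:
        # every resample reuses the same design matrix; all replicate
        # refits vectorize into one profile-ML call
        draws = [
            rng.choice(participants, size=participants.size, replace=True)
            for _ in range(n_boot)
        ]
        idxs = [np.concatenate([rows_of[g] for g in d]) for d in draws]
        Y = np.concatenate([null_flat[idx] for idx in idxs], axis=1)
        # rows are stacked participant-block-wise; rebuild the matching design
        block = blocks[0]
        Xb = np.concatenate([block] * participants.size, axis=0)
        groups_b = np.repeat(np.arange(participants.size), block.shape[0])
        beta, se, _, _ = _fit_random_intercept_ml(Y, Xb, groups_b)
        z = beta[eff_idx] / se[eff_idx]
        p = 2.0 * stats.norm.sf(np.abs(z))
        n_mask = int(maps.mask.sum())
        for b in range(n_boot):
            sl = slice(b * n_mask, (b + 1) * n_mask)
            p_map = np.ones(rows * cols)
            p_map[maps.mask.ravel()] = p[sl]
            coef_map = np.zeros(rows * cols)
            coef_map[maps.mask.ravel()] = beta[eff_idx, sl]
            boot_clusters = _clusters(
                p_map.reshape(rows, cols), coef_map.reshape(rows, cols),
                maps.mask, threshold,
            )
            null_max[b] = max((abs(m) for _, m in boot_clusters), default=0.0)
    else:
        for b in range(n_boot):
            draw = rng.choice(participants, size=participants.size, replace=True)
            idx = np.concatenate([rows_of[g] for g in draw])
            # resampled participants are treated as distinct groups
            boot_design = design.iloc[idx].copy()
            boot_design["participant"] = np.repeat(
                np.arange(draw.size), [rows_of[g].size for g in draw]
            )
            boot_maps = fit_pixel_models(null_stack[idx], boot_design)
            boot_clusters = _clusters(
                boot_maps.p[effect], boot_maps.coef[effect], boot_maps.mask,
                threshold,
            )
            null_max[b] = max((abs(m) for _, m in boot_clusters), default=0.0)

    clusters = [
        Cluster(
            pixels=pix,
            mass=mass,
            p_boot=float((1 + np.sum(null_max >= abs(mass) - 1e-12)) / (1 + n_boot)),
        )
        for pix, mass in observed
    ]
    return ClusterResult(
        clusters=clusters, threshold=threshold, kernel_sd=None, null_max_mass=null_max
    )
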