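"""Synthetic multi-subject V1 fMRI cohorts.

Each subject's run is the sum of three sources:

* a *common response*: one condition-specific spatial pattern, shared by the
  whole cohort, times the canonical-HRF-convolved stimulation boxcar;
* an *idiosyncratic evoked response*: the same regressor times a
  subject-specific gain perturbation and a small subject-specific spatial
  pattern;
* *background activity*: temporally smooth (AR(1)) noise whose vertex
  covariance carries a planted, condition-dependent network structure
  during (lag-shifted) stimulation epochs and a baseline covariance
  elsewhere.

Planted structure is expressed per condition as correlation increments on
named edge groups ("interhemispheric", "intrahemispheric", or any of the
ten quadrant sub-network labels) and realized as disjoint vertex-pair
matchings, which keeps the covariance positive definite for |rho| < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import CONDITIONS, STIM_S, BlockSchedule
from .preprocess import DEFAULT_LAG_S, evoked_regressor
from .retinotopy import (
    INTERHEMISPHERIC,
    INTRAHEMISPHERIC,
    SUBNETWORK_LABELS,
    RetinotopicMap,
    subnetwork_label,
)


@dataclass(frozen=True)
class EffectSpec:
    """Condition-effect parameters of the cohort generator.

    All-zero fields yield i.i.d. noise (no condition information anywhere in
    the data).  ``common_gain`` maps condition -> amplitude of the shared
    evoked response; ``planted_network`` maps condition -> {edge group ->
    correlation increment}.
    """

    common_gain: dict[str, float] = field(default_factory=dict)
    idio_gain_sd: float = 0.0
    idio_pattern_sd: float = 0.0
    bg_sd: float = 1.0
    ar_coef: float = 0.3
    planted_network: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def null(cls, bg_sd: float = 1.0) -> "EffectSpec":
        """Pure background, no condition effect of any kind."""
        return cls(bg_sd=bg_sd)

    @classmethod
    def level_network(
        cls,
        rho: float = 0.3,
        common_gain: float = 0.5,
        idio_gain_sd: float = 0.2,
        idio_pattern_sd: float = 0.1,
        bg_sd: float = 1.0,
    ) -> "EffectSpec":
        """Default positive control: Global conditions raise interhemispheric
        background coupling, Local conditions raise intra-hemispheric
        coupling; evoked amplitudes identical across conditions (the evoked
        response carries no Level information, the network structure does).
        """
        return cls(
            common_gain={c: common_gain for c in CONDITIONS},
            idio_gain_sd=idio_gain_sd,
            idio_pattern_sd=idio_pattern_sd,
            bg_sd=bg_sd,
            planted_network={
                "EG": {"interhemispheric": rho},
                "UG": {"interhemispheric": rho},
                "EL": {"intrahemispheric": rho},
                "UL": {"intrahemispheric": rho},
            },
        )


@dataclass
class RunData:
    bold: np.ndarray  # time x vertex
    tr: float
    confounds: np.ndarray  # time x k


@dataclass
class SubjectDataset:
    subject_id: str
    runs: list[RunData]
    schedule: BlockSchedule
    rmap: RetinotopicMap
    seed: int

    @property
    def n_vertices(self) -> int:
        return self.runs[0].bold.shape[1]


def _edges_of_group(rmap: RetinotopicMap, group: str) -> set[str]:
    if group == "interhemispheric":
        return set(INTERHEMISPHERIC)
    if group == "intrahemispheric":
        return set(INTRAHEMISPHERIC)
    if group in SUBNETWORK_LABELS:
        return {group}
    raise ValueError(f"unknown edge group {group!r}")


def _matching_for_labels(
    rmap: RetinotopicMap, labels: set[str], used: set[int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Greedy disjoint vertex-pair matching whose edges carry the labels."""
    quad = rmap.quadrant
    order = rng.permutation(rmap.n_vertices)
    pairs: list[tuple[int, int]] = []
    free = [int(v) for v in order if int(v) not in used]
    while len(free) >= 2:
        i = free.pop(0)
        match = None
        for pos, j in enumerate(free):
            if subnetwork_label(quad[i], quad[j]) in labels:
                match = pos
                break
        if match is None:
            continue
        j = free.pop(match)
        pairs.append((i, j))
        used.update((i, j))
    return pairs


def group_matchings(
    rmap: RetinotopicMap,
    groups: list[str],
    rng: np.random.Generator,
) -> dict[str, list[tuple[int, int]]]:
    """One disjoint vertex-pair matching per edge group, drawn once.

    Conditions that plant covariance on the same group share the same
    edges — the planted network for an abstract property (e.g. Level) is
    then identical across letters, which is what lets cross-classification
    transfer learning between condition pairs.
    """
    used: set[int] = set()
    return {
        g: _matching_for_labels(rmap, _edges_of_group(rmap, g), used, rng)
        for g in groups
    }


def _covariance_from_matchings(
    rmap: RetinotopicMap,
    increments: dict[str, float],
    matchings: dict[str, list[tuple[int, int]]],
    condition: str = "",
) -> np.ndarray:
    sigma = np.eye(rmap.n_vertices)
    for group, rho in increments.items():
        if abs(rho) >= 1.0:
            raise ValueError(
                f"planted covariance for condition {condition!r} is not "
                f"positive semi-definite: |rho| >= 1 in group {group!r}"
            )
        for i, j in matchings[group]:
            sigma[i, j] = sigma[j, i] = rho
    eigmin = np.linalg.eigvalsh(sigma)[0]
    if eigmin < -1e-10:
        raise ValueError(
            f"planted covariance for condition {condition!r} is not positive "
            f"semi-definite (smallest eigenvalue {eigmin:.3g})"
        )
    return sigma


def planted_covariance(
    rmap: RetinotopicMap,
    increments: dict[str, float],
    rng: np.random.Generator,
    condition: str = "",
) -> np.ndarray:
    """Unit-variance covariance with matched-pair correlation increments."""
    matchings = group_matchings(rmap, list(increments), rng)
    return _covariance_from_matchings(rmap, increments, matchings, condition)


def _stimulation_sample_masks(
    schedule: BlockSchedule, run: int, n: int, lag_s: float
) -> dict[str, np.ndarray]:
    """Boolean TR-sample masks of the lag-shifted stimulation epochs."""
    tr = schedule.tr
    n_win = int(round(STIM_S / tr))
    masks = {}
    for cond in CONDITIONS:
        mask = np.zeros(n, dtype=bool)
        for block in schedule.blocks_of(run, cond):
            start = int(round((block.stim_onset_s + lag_s) / tr))
            mask[start : min(start + n_win, n)] = True
        masks[cond] = mask
    return masks


def _ar1(innovations: np.ndarray, phi: float) -> np.ndarray:
    """Stationary AR(1) filtering along axis 0 (unit marginal variance)."""
    if phi == 0.0:
        return innovations
    out = np.empty_like(innovations)
    out[0] = innovations[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, innovations.shape[0]):
        out[t] = phi * out[t - 1] + scale * innovations[t]
    return out


def _pseudo_motion(rng: np.random.Generator, n: int, k: int = 6) -> np.ndarray:
    """Slow random-walk confounds standing in for head-motion parameters."""
    steps = rng.normal(0.0, 1.0, (n, k))
    walk = np.cumsum(steps, axis=0)
    walk -= walk.mean(axis=0)
    return walk / np.maximum(walk.std(axis=0), 1e-12)


def simulate_cohort(
    n_subjects: int,
    rmap: RetinotopicMap,
    schedule: BlockSchedule,
    effect: EffectSpec,
    seed: int = 0,
    lag_s: float = DEFAULT_LAG_S,
    n_confounds: int = 6,
) -> list[SubjectDataset]:
    """Generate a cohort of subject datasets under the source model.

    Fully reproducible: identical (seed, effect, schedule, map) arguments
    give bitwise-identical cohorts.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    v = rmap.n_vertices
    n = schedule.n_samples_per_run
    tr = schedule.tr

    # cohort-level ingredients (drawn once, shared by all subjects)
    common_patterns = {c: rng.normal(0.0, 1.0, v) for c in CONDITIONS}
    all_groups = sorted(
        {g for incr in effect.planted_network.values() for g in incr}
    )
    matchings = group_matchings(rmap, all_groups, rng)
    chol = {}
    for cond in CONDITIONS:
        incr = effect.planted_network.get(cond, {})
        sigma = (
            _covariance_from_matchings(rmap, incr, matchings, cond)
            if incr
            else np.eye(v)
        )
        chol[cond] = np.linalg.cholesky(sigma)
    regressors = [
        {
            c: evoked_regressor(
                [b.stim_onset_s for b in schedule.blocks_of(run, c)], STIM_S, n, tr
            )
            for c in CONDITIONS
        }
        for run in range(schedule.n_runs)
    ]
    masks = [
        _stimulation_sample_masks(schedule, run, n, lag_s)
        for run in range(schedule.n_runs)
    ]

    cohort = []
    for s in range(n_subjects):
        gains = {
            c: effect.common_gain.get(c, 0.0)
            * (1.0 + rng.normal(0.0, effect.idio_gain_sd))
            for c in CONDITIONS
        }
        idio_patterns = {
            c: rng.normal(0.0, effect.idio_pattern_sd, v) if effect.idio_pattern_sd
            else np.zeros(v)
            for c in CONDITIONS
        }
        runs = []
        for run in range(schedule.n_runs):
            noise = _ar1(rng.normal(0.0, 1.0, (n, v)), effect.ar_coef)
            bg = noise.copy()
            for cond in CONDITIONS:
                m = masks[run][cond]
                bg[m] = noise[m] @ chol[cond].T
            bold = effect.bg_sd * bg
            for cond in CONDITIONS:
                pattern = gains[cond] * (common_patterns[cond] + idio_patterns[cond])
                bold = bold + np.outer(regressors[run][cond], pattern)
            confounds = _pseudo_motion(rng, n, n_confounds)
            # confound leakage into the data scales with the noise level so
            # the noise-free limit is exactly the shared evoked signal
            bold = bold + confounds @ rng.normal(
                0.0, 0.1 * effect.bg_sd, (n_confounds, v)
            )
            runs.append(RunData(bold=bold, tr=tr, confounds=confounds))
        cohort.append(
            SubjectDataset(
                subject_id=f"sub-{s:02d}",
                runs=runs,
                schedule=schedule,
                rmap=rmap,
                seed=seed,
            )
        )
    return cohort
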