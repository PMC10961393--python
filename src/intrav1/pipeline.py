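"""End-to-end orchestration: cohort -> features -> classification reports.

The three preprocessing schemes map onto feature tables as follows:

* ``cr``   — nuisance-regressed raw series; common-response matrices
  (each subject correlated with the grand average of the others);
* ``hrfc`` — canonical-HRF deconvolution residuals; within-subject matrices;
* ``fir``  — FIR deconvolution residuals; within-subject matrices;
* ``raw``  — nuisance-regressed series, within-subject matrices (not one of
  the study's schemes, useful for diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import SubjectDataset
from .connectivity import common_response_matrix, to_features, within_subject_matrix
from .design import CONDITIONS
from .mvpa import (
    ConditionPair,
    fisher_combine,
    permutation_test,
)
from .preprocess import (
    DEFAULT_LAG_S,
    ConditionSeries,
    deconvolve_glm,
    nuisance_regress,
    segment_concatenate,
)

SCHEMES = ("cr", "hrfc", "fir")

#: the four specific contrasts: (name, condition pair, class labels)
SPECIFIC_CONTRASTS = {
    "level_E": (("EG", "EL"), ("Global", "Local")),
    "level_U": (("UG", "UL"), ("Global", "Local")),
    "letter_G": (("EG", "UG"), ("E", "U")),
    "letter_L": (("EL", "UL"), ("E", "U")),
}
#: the two abstract cross-classifications: (pair A, pair B, class labels)
CROSS_CONTRASTS = {
    "abstract_level": (("EG", "EL"), ("UG", "UL"), ("Global", "Local")),
    "abstract_letter": (("EG", "UG"), ("EL", "UL"), ("E", "U")),
}


@dataclass
class FeatureTable:
    """Rectified Fisher-z edge features for every subject and condition."""

    subjects: tuple[str, ...]
    scheme: str
    X: np.ndarray  # n_subjects x 4 x n_edges (condition order = CONDITIONS)

    @property
    def n_edges(self) -> int:
        return self.X.shape[2]

    def pair(
        self, cond_a: str, cond_b: str, labels: tuple[str, str]
    ) -> ConditionPair:
        ia, ib = CONDITIONS.index(cond_a), CONDITIONS.index(cond_b)
        return ConditionPair(
            subjects=self.subjects,
            conditions=(cond_a, cond_b),
            labels=labels,
            X=self.X[:, (ia, ib), :],
        )


def subject_condition_series(
    ds: SubjectDataset, scheme: str, lag_s: float = DEFAULT_LAG_S
) -> dict[str, ConditionSeries]:
    """Run the per-subject preprocessing chain for one scheme."""
    resid = [
        nuisance_regress(run.bold, run.confounds, run.tr) for run in ds.runs
    ]
    if scheme == "hrfc":
        resid = [
            deconvolve_glm(r, ds.schedule, run, basis="canonical")
            for run, r in enumerate(resid)
        ]
    elif scheme == "fir":
        resid = [
            deconvolve_glm(r, ds.schedule, run, basis="FIR")
            for run, r in enumerate(resid)
        ]
    elif scheme not in ("raw", "cr"):
        raise ValueError(f"unknown scheme {scheme!r}")
    label = {"cr": "CR", "hrfc": "HRFc", "fir": "FIR", "raw": "raw"}[scheme]
    return {
        cond: segment_concatenate(
            resid, ds.schedule, cond, lag_s=lag_s,
            subject_id=ds.subject_id, scheme=label,
        )
        for cond in CONDITIONS
    }


def cohort_features(
    cohort: list[SubjectDataset], scheme: str, lag_s: float = DEFAULT_LAG_S
) -> FeatureTable:
    """Feature table for a whole cohort under one preprocessing scheme."""
    series = [subject_condition_series(ds, scheme, lag_s) for ds in cohort]
    rows = []
    for i, ds in enumerate(cohort):
        feats = []
        for cond in CONDITIONS:
            if scheme == "cr":
                others = [series[j][cond] for j in range(len(cohort)) if j != i]
                matrix = common_response_matrix(series[i][cond], others)
            else:
                matrix = within_subject_matrix(series[i][cond])
            feats.append(to_features(matrix).values)
        rows.append(np.stack(feats))
    return FeatureTable(
        subjects=tuple(ds.subject_id for ds in cohort),
        scheme=scheme,
        X=np.stack(rows),
    )


def features_from_matrices(
    matrices: dict[str, dict[str, np.ndarray]], scheme: str = ""
) -> FeatureTable:
    """Feature table from precomputed correlation matrices.

    ``matrices[subject][condition]`` is a symmetric correlation matrix;
    used by the gaze simulation, whose node space replaces V1 vertices.
    """
    from .connectivity import ConnectivityMatrix

    subjects = tuple(matrices)
    rows = []
    for subject in subjects:
        feats = []
        for cond in CONDITIONS:
            cm = ConnectivityMatrix(subject, cond, scheme, matrices[subject][cond])
            feats.append(to_features(cm).values)
        rows.append(np.stack(feats))
    return FeatureTable(subjects=subjects, scheme=scheme, X=np.stack(rows))


def specific_tests(
    table: FeatureTable, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Inter-subject LOSO classification of the four specific contrasts.

    The two instances of each classifier type (level for E and for U;
    letter for Global and for Local) are averaged and their permutation
    p-values combined with Fisher's formula.
    """
    rng = np.random.default_rng(seed)
    out: dict = {}
    for name, (conds, labels) in SPECIFIC_CONTRASTS.items():
        pair = table.pair(*conds, labels)
        out[name] = permutation_test(
            pair, mode="loso", n_perm=n_perm, seed=int(rng.integers(2**31))
        )
    for family, members in (("level", ("level_E", "level_U")),
                            ("letter", ("letter_G", "letter_L"))):
        accs = [out[m].accuracy for m in members]
        ps = [out[m].p_value for m in members]
        out[family] = {
            "accuracy": float(np.mean(accs)),
            "combined_p": fisher_combine(ps),
        }
    return out


def cross_tests(
    table: FeatureTable, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Within-sample two-direction cross-classification of Level and Letter."""
    rng = np.random.default_rng(seed)
    out: dict = {}
    for name, (conds_a, conds_b, labels) in CROSS_CONTRASTS.items():
        pair_a = table.pair(*conds_a, labels)
        pair_b = table.pair(*conds_b, labels)
        out[name] = permutation_test(
            pair_a, pair_b, mode="cross", n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
    return out


def decode_cohort(
    cohort: list[SubjectDataset],
    schemes: tuple[str, ...] = SCHEMES,
    n_perm: int = 1000,
    seed: int = 0,
    lag_s: float = DEFAULT_LAG_S,
) -> dict:
    """Full classification report over preprocessing schemes."""
    report: dict = {}
    for si, scheme in enumerate(schemes):
        table = cohort_features(cohort, scheme, lag_s=lag_s)
        report[scheme] = {
            "specific": specific_tests(table, n_perm=n_perm, seed=seed + 7 * si),
            "cross": cross_tests(table, n_perm=n_perm, seed=seed + 7 * si + 3),
        }
    return report


def run_sim_experiment(
    trajectories: dict[str, dict[str, list]],
    stimuli: dict[str, np.ndarray],
    bank,
    tr: float = 2.5,
    n_perm: int = 1000,
    seed: int = 0,
    tests: tuple[str, ...] = ("specific", "cross"),
) -> dict:
    """Gaze-simulation experiment: node correlation matrices -> classifiers.

    ``trajectories[subject][condition]`` is a list of per-block
    ``GazeTrajectory`` objects; ``stimuli[condition]`` is the screen image.
    For each subject and condition the simulated node time series of all
    blocks are concatenated, correlated, and pushed through the identical
    feature and classification pipeline used for the fMRI-like data.
    """
    from .gaborsim import fixation_node_responses, simulate_bold

    matrices: dict[str, dict[str, np.ndarray]] = {}
    for subject, per_cond in trajectories.items():
        matrices[subject] = {}
        for cond in CONDITIONS:
            segments = []
            for traj in per_cond[cond]:
                responses = fixation_node_responses(bank, stimuli[cond], traj)
                sim = simulate_bold(responses, traj, tr=tr)
                segments.append(sim.responses.T)  # time x node
            data = np.concatenate(segments, axis=0)
            series = ConditionSeries(
                subject_id=subject, condition=cond, scheme="sim",
                data=data,
                segment_boundaries=np.arange(len(segments)) * segments[0].shape[0],
            )
            matrices[subject][cond] = within_subject_matrix(series).values
    table = features_from_matrices(matrices, scheme="sim")
    report: dict = {"n_nodes": bank.n_nodes, "n_edges": table.n_edges}
    if "specific" in tests:
        report["specific"] = specific_tests(table, n_perm=n_perm, seed=seed)
    if "cross" in tests:
        report["cross"] = cross_tests(table, n_perm=n_perm, seed=seed + 1)
    return report
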