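"""Interpretation of the abstract-Level cross-classifier.

Backward-model SVM weights are converted to forward-model activation
patterns with the Haufe transform (a = Cov(X) w for a single linear
discriminant; the scalar latent variance only rescales the map).  Stability
is assessed with a participant bootstrap: in each replicate the two
direction-specific classifiers are retrained on resampled subjects and
their transformed maps compared with Kendall's W; 95% bias-corrected and
accelerated (BCa) intervals summarize the concordance.  The per-replicate
direction-averaged maps are reduced to a per-edge median map whose upper
and lower 2.5% tails are the Local- and Global-supporting significant
edges, counted per quadrant sub-network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import SubNetworkPartition
from .mvpa import ConditionPair, train_svm, ttest_select
from .retinotopy import SUBNETWORK_LABELS

DEFAULT_N_BOOT = 1000


@dataclass
class TransformedWeightMap:
    values: np.ndarray  # per-edge activation on the full edge index
    direction: str = ""
    replicate: int = -1


@dataclass
class WeightMapSummary:
    median_map: np.ndarray
    local_edges: np.ndarray  # top 2.5% (positive, supporting Local)
    global_edges: np.ndarray  # bottom 2.5% (negative, supporting Global)
    kendall_w_samples: np.ndarray | None = None
    w_original: float | None = None
    w_ci: tuple[float, float] | None = None


def haufe_transform(
    model, X_train: np.ndarray, direction: str = "", replicate: int = -1
) -> TransformedWeightMap:
    """Forward-model activation pattern of a fitted linear classifier.

    ``a = Cov(X_retained) @ w`` mapped back onto the full edge index with
    zeros outside the retained set.  Positive activations support the
    positive class of the model's coding (Local for a Level contrast).
    """
    if X_train.shape[0] < 2:
        raise ValueError("covariance needs at least 2 samples")
    Xr = X_train[:, model.retained]
    cov = np.cov(Xr, rowvar=False)
    cov = np.atleast_2d(cov)
    activation = cov @ model.w
    full = np.zeros(X_train.shape[1])
    full[model.retained] = activation
    return TransformedWeightMap(values=full, direction=direction, replicate=replicate)


def _train_and_transform(pair: ConditionPair, idx: np.ndarray, alpha: float, C: float,
                         direction: str, replicate: int) -> TransformedWeightMap:
    Xb = pair.X[idx].reshape(-1, pair.X.shape[2])
    yb = np.tile(np.asarray(pair.labels, dtype=object), idx.size)
    retained = ttest_select(Xb, yb, alpha=alpha)
    model = train_svm(Xb, yb, retained, C=C)
    return haufe_transform(model, Xb, direction=direction, replicate=replicate)


def bootstrap_weight_maps(
    pair_a: ConditionPair,
    pair_b: ConditionPair,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    alpha: float = 0.01,
    C: float = 1.0,
) -> list[tuple[TransformedWeightMap, TransformedWeightMap]]:
    """Participant bootstrap of the two direction-specific classifiers.

    Each replicate resamples subjects with replacement, retrains the
    classifier on each training pair, and emits its Haufe-transformed map.
    Replicates that draw a single unique subject are redrawn.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if pair_a.subjects != pair_b.subjects:
        raise ValueError("the two pairs must hold the same subjects")
    rng = np.random.default_rng(seed)
    n = pair_a.n_subjects
    out = []
    for rep in range(n_boot):
        idx = rng.integers(0, n, n)
        while np.unique(idx).size < 2:
            idx = rng.integers(0, n, n)
        map_a = _train_and_transform(pair_a, idx, alpha, C, "A->B", rep)
        map_b = _train_and_transform(pair_b, idx, alpha, C, "B->A", rep)
        out.append((map_a, map_b))
    return out


def kendalls_w(rankings: np.ndarray) -> float:
    """Kendall's coefficient of concordance with midrank tie correction.

    ``rankings`` is an m x n array of scores (m raters, n items); scores
    are converted to midranks internally.  W = 1 for identical rankings;
    for m = 2 raters W = (1 + rho_spearman) / 2, so two independent random
    rankings average W = 0.5 and exact reversal gives W = 0.
    """
    scores = np.atleast_2d(np.asarray(rankings, dtype=float))
    m, n = scores.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 items")
    ranks = np.vstack([stats.rankdata(row) for row in scores])
    if np.any(np.ptp(ranks, axis=1) == 0):
        raise ValueError("a rater ranked all items identically; W undefined")
    totals = ranks.sum(axis=0)
    s = np.sum((totals - totals.mean()) ** 2)
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    denom = m**2 * (n**3 - n) - m * tie_term
    return float(12.0 * s / denom)


def bca_ci(
    bootstrap_stats: np.ndarray,
    original_stat: float,
    level: float = 0.95,
    jackknife_stats: np.ndarray | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap percentile interval.

    The bias correction z0 comes from the fraction of replicates below the
    original statistic; the acceleration a from the jackknife skewness
    (a = 0, i.e. plain bias correction, when no jackknife values are
    given).  With z0 = 0 and a = 0 this reduces exactly to the plain
    percentile interval.
    """
    boot = np.sort(np.asarray(bootstrap_stats, dtype=float))
    if boot.size < 2:
        raise ValueError("need bootstrap replicates")
    if np.ptp(boot) == 0:
        return float(boot[0]), float(boot[0])
    frac = np.clip(np.mean(boot < original_stat), 1e-9, 1 - 1e-9)
    z0 = stats.norm.ppf(frac)
    if jackknife_stats is not None and len(jackknife_stats) > 2:
        jk = np.asarray(jackknife_stats, dtype=float)
        d = jk.mean() - jk
        denom = 6.0 * np.sum(d**2) ** 1.5
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    else:
        a = 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        z = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
        out.append(float(np.quantile(boot, np.clip(adj, 0.0, 1.0))))
    return out[0], out[1]


def concordance_samples(
    replicate_pairs: list[tuple[TransformedWeightMap, TransformedWeightMap]],
) -> np.ndarray:
    """Per-replicate Kendall's W between the two direction maps.

    Rankings are taken over the union of edges retained in either
    direction (edges untouched by both classifiers are excluded rather
    than midranked at zero).
    """
    ws = []
    for map_a, map_b in replicate_pairs:
        union = (map_a.values != 0) | (map_b.values != 0)
        ws.append(kendalls_w(np.vstack([map_a.values[union], map_b.values[union]])))
    return np.asarray(ws)


def summarize_maps(
    replicate_pairs: list[tuple[TransformedWeightMap, TransformedWeightMap]],
    tail: float = 0.025,
) -> WeightMapSummary:
    """Median direction-averaged map and its significant-edge tails.

    The top ``tail`` fraction of nonzero median weights supports Local, the
    bottom fraction Global; counts use the ceiling and threshold ties break
    by edge index.
    """
    if len(replicate_pairs) < 2:
        raise ValueError("need at least 2 replicates")
    averaged = np.vstack(
        [(a.values + b.values) / 2.0 for a, b in replicate_pairs]
    )
    median_map = np.median(averaged, axis=0)
    nonzero = np.flatnonzero(median_map != 0)
    k = int(np.ceil(tail * nonzero.size))
    if 2 * k > nonzero.size:
        raise ValueError("too few nonzero edges for disjoint significance tails")
    order = nonzero[np.argsort(median_map[nonzero], kind="stable")]
    return WeightMapSummary(
        median_map=median_map,
        local_edges=np.sort(order[-k:]) if k else np.array([], dtype=int),
        global_edges=np.sort(order[:k]) if k else np.array([], dtype=int),
    )


def analyze_weight_maps(
    pair_a: ConditionPair,
    pair_b: ConditionPair,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = 0.95,
    jackknife: bool = True,
) -> WeightMapSummary:
    """Full weight-map pipeline: bootstrap, median map, W, BCa interval."""
    reps = bootstrap_weight_maps(pair_a, pair_b, n_boot=n_boot, seed=seed)
    summary = summarize_maps(reps)
    ws = concordance_samples(reps)
    full_idx = np.arange(pair_a.n_subjects)
    alpha, C = 0.01, 1.0
    orig_pair = (
        _train_and_transform(pair_a, full_idx, alpha, C, "A->B", -1),
        _train_and_transform(pair_b, full_idx, alpha, C, "B->A", -1),
    )
    w_orig = concordance_samples([orig_pair])[0]
    jk = None
    if jackknife and pair_a.n_subjects > 3:
        jk = []
        for s in range(pair_a.n_subjects):
            idx = np.delete(full_idx, s)
            pair = (
                _train_and_transform(pair_a, idx, alpha, C, "A->B", -1),
                _train_and_transform(pair_b, idx, alpha, C, "B->A", -1),
            )
            jk.append(concordance_samples([pair])[0])
        jk = np.asarray(jk)
    summary.kendall_w_samples = ws
    summary.w_original = float(w_orig)
    summary.w_ci = bca_ci(ws, w_orig, level=level, jackknife_stats=jk)
    return summary


def subnetwork_counts(
    summary: WeightMapSummary, partition: SubNetworkPartition
) -> dict[str, dict[str, int]]:
    """Significant-edge counts per supported level and sub-network."""
    counts = {
        "Local": {label: 0 for label in SUBNETWORK_LABELS},
        "Global": {label: 0 for label in SUBNETWORK_LABELS},
    }
    for level, edges in (("Local", summary.local_edges),
                         ("Global", summary.global_edges)):
        for e in edges:
            counts[level][str(partition.labels[e])] += 1
    return counts


def assemble_contingency(
    per_scheme: dict[str, dict[str, dict[str, int]]],
) -> np.ndarray:
    """Stack per-scheme counts into the scheme x level x sub-network table."""
    schemes = sorted(per_scheme)
    table = np.zeros((len(schemes), 2, len(SUBNETWORK_LABELS)), dtype=int)
    for si, scheme in enumerate(schemes):
        for li, level in enumerate(("Global", "Local")):
            for ki, label in enumerate(SUBNETWORK_LABELS):
                table[si, li, ki] = per_scheme[scheme][level][label]
    return table


def heterogeneity_test(
    tables: np.ndarray,
    n_mc: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Chi-square homogeneity of category distributions across tables.

    ``tables`` is an (n_margins, n_categories) count array (e.g. the 6
    scheme-by-level margins over the 10 sub-networks).  When any expected
    count falls below 5 the p-value is computed by Monte-Carlo simulation
    under the pooled distribution (add-one estimator).
    """
    tables = np.atleast_2d(np.asarray(tables, dtype=float))
    if tables.shape[0] < 2:
        raise ValueError("homogeneity needs at least 2 tables")
    totals = tables.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a table has zero total count")
    tables = tables[:, tables.sum(axis=0) > 0]
    stat = _chi2_stat(tables)
    expected = np.outer(totals, tables.sum(axis=0)) / tables.sum()
    if expected.min() >= 5:
        df = (tables.shape[0] - 1) * (tables.shape[1] - 1)
        return stat, float(stats.chi2.sf(stat, df))
    rng = np.random.default_rng(seed)
    pooled = tables.sum(axis=0) / tables.sum()
    sims = np.array(
        [
            _chi2_stat(np.vstack([rng.multinomial(int(t), pooled) for t in totals]))
            for _ in range(n_mc)
        ]
    )
    return stat, float((1 + np.sum(sims >= stat - 1e-12)) / (1 + n_mc))


def _chi2_stat(table: np.ndarray) -> float:
    """Pearson chi-square statistic tolerating empty columns."""
    table = table[:, table.sum(axis=0) > 0]
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
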