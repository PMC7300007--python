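"""Global proteotype analysis: spectral-count normalization and
drug-target-sorted gene-set enrichment.

Spectral counts (proteins x samples) are globally normalized (per-sample
scaling to the cohort median library size), log2(x+1)-transformed and
converted to per-protein z-scores across samples.  Proteins are then ranked
by the association of their z-score profile with a targeted drug-target
abundance vector (Pearson correlation by default, signal-to-noise between
high/low target halves as an alternative), and gene sets are scored with
the weighted Kolmogorov-Smirnov running-sum enrichment statistic.
Significance comes from a phenotype permutation null: the target vector's
sample labels are permuted, the ranking and enrichment scores recomputed,
and per-set p-values and normalized enrichment scores (NES) derived from
the same-sign null distribution, with Benjamini-Hochberg FDR across sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_counts",
    "CountZScoreNormalizer",
    "rank_by_target",
    "EnrichmentScore",
    "enrichment_score",
    "permutation_test",
    "TargetSortedGSEA",
    "plot_enrichment",
]


def _scale_columns(counts: pd.DataFrame, method: str) -> pd.DataFrame:
    totals = counts.sum(axis=0).to_numpy(float)
    if (totals == 0).any():
        bad = list(counts.columns[totals == 0])
        raise ValueError(f"sample(s) with zero total counts: {bad}")
    if method == "median_total":
        target = float(np.median(totals))
        return counts * (target / totals)
    if method == "total":
        target = float(totals.mean())
        return counts * (target / totals)
    if method == "quantile":
        arr = counts.to_numpy(float)
        order = np.argsort(arr, axis=0, kind="mergesort")
        ranked = np.take_along_axis(arr, order, axis=0)
        mean_profile = ranked.mean(axis=1)
        out = np.empty_like(arr)
        np.put_along_axis(out, order, mean_profile[:, None], axis=0)
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    raise ValueError(f"unknown normalization method: {method!r}")


def normalize_counts(
    counts: pd.DataFrame,
    method: str = "median_total",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Spectral counts -> per-protein z-scores.

    Steps: (1) scale each sample's counts so column totals match the cohort
    median total (``method="median_total"``; ``"total"`` scales to the mean
    total, ``"quantile"`` quantile-normalizes columns); (2) log2(x +
    pseudocount); (3) z-score each protein across samples (ddof=1).
    Constant proteins become all-zero rows.
    """
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 proteins and 2 samples")
    scaled = _scale_columns(counts, method)
    logged = np.log2(scaled + pseudocount)
    mu = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    z = logged.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return z


class CountZScoreNormalizer(BaseEstimator):
    """Scikit-learn style wrapper around :func:`normalize_counts`.

    Operates on proteins x samples DataFrames (the omics convention, with
    samples as columns).  ``fit`` records the scaling target from the
    training cohort; ``transform`` applies scaling, log transform and
    per-protein z-scoring to the given matrix.
    """

    def __init__(self, method: str = "median_total", pseudocount: float = 1.0):
        self.method = method
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y=None) -> "CountZScoreNormalizer":
        totals = X.sum(axis=0).to_numpy(float)
        if (totals == 0).any():
            raise ValueError("sample(s) with zero total counts")
        self.library_target_ = float(np.median(totals))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "library_target_")
        return normalize_counts(X, method=self.method, pseudocount=self.pseudocount)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def _target_vector(z: pd.DataFrame, target) -> np.ndarray:
    if isinstance(target, pd.Series):
        target = target.reindex(z.columns)
        if target.isna().any():
            raise ValueError("target vector missing values for some samples")
        t = target.to_numpy(float)
    else:
        t = np.asarray(target, dtype=float)
        if t.shape != (z.shape[1],):
            raise ValueError("target vector length must match the sample count")
    if np.ptp(t) == 0:
        raise ValueError("target abundance has zero variance")
    return t


def _correlation_scores(zmat: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of *zmat* with *t*; constant rows -> 0."""
    zc = zmat - zmat.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    denom = np.sqrt((zc**2).sum(axis=1)) * math.sqrt(float((tc**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (zc @ tc) / denom
    return np.where(denom > 0, r, 0.0)


def _s2n_scores(zmat: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Signal-to-noise between the high- and low-target sample halves."""
    order = np.argsort(-t, kind="mergesort")
    half = len(t) // 2
    hi, lo = order[:half], order[half:]
    mu_hi, mu_lo = zmat[:, hi].mean(axis=1), zmat[:, lo].mean(axis=1)
    sd_hi, sd_lo = zmat[:, hi].std(axis=1, ddof=1), zmat[:, lo].std(axis=1, ddof=1)
    denom = np.maximum(sd_hi + sd_lo, 1e-12)
    return (mu_hi - mu_lo) / denom


_RANKINGS = {"pearson": _correlation_scores, "s2n": _s2n_scores}


def rank_by_target(z: pd.DataFrame, target, ranking: str = "pearson") -> pd.DataFrame:
    """Rank proteins by association of their profile with a target vector.

    *z* is proteins x samples; *target* is the per-sample drug-target
    abundance (array in column order, or a Series indexed by sample).
    Returns a DataFrame ``(protein, score)`` sorted by descending score,
    ties broken by protein identifier.
    """
    t = _target_vector(z, target)
    try:
        scores = _RANKINGS[ranking](z.to_numpy(float), t)
    except KeyError:
        raise ValueError(f"unknown ranking metric: {ranking!r}") from None
    out = pd.DataFrame({"protein": z.index, "score": scores})
    return out.sort_values(
        ["score", "protein"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class EnrichmentScore:
    """Enrichment score with its running-sum profile.

    ``running_sum[i]`` is the deviation after walking the first ``i + 1``
    ranked proteins; ``es`` is the signed maximum deviation.
    """

    es: float
    running_sum: np.ndarray
    hit_positions: np.ndarray
    n_members_present: int


def _es_from_sorted(
    scores_sorted: np.ndarray, hit_mask: np.ndarray, weight_p: float
) -> tuple[float, np.ndarray]:
    """Weighted KS running sum over one ranking for one set (2-D capable).

    ``hit_mask`` may be (N,) or (n_sets, N); returns (es, running_sum) with
    matching leading dimension.
    """
    hit = np.atleast_2d(hit_mask).astype(float)
    n = scores_sorted.shape[0]
    w = np.abs(scores_sorted) ** weight_p if weight_p != 0 else np.ones(n)
    hw = hit * w
    denom_hit = hw.sum(axis=1, keepdims=True)
    n_hits = hit.sum(axis=1, keepdims=True)
    # all-hit weights zero: fall back to unweighted steps for those sets
    flat = (denom_hit == 0) & (n_hits > 0)
    if flat.any():
        hw = np.where(flat, hit, hw)
        denom_hit = np.where(flat, n_hits, denom_hit)
    # sets with no member present are reported as non-evaluable upstream;
    # keep the arithmetic finite for them
    denom_hit = np.where(denom_hit == 0, 1.0, denom_hit)
    p_hit = np.cumsum(hw, axis=1) / denom_hit
    n_miss = n - n_hits
    p_miss = np.cumsum(1.0 - hit, axis=1) / n_miss
    dev = p_hit - p_miss
    # Signed maximum deviation; when the positive and negative extrema tie
    # in magnitude (within 1e-9) the positive deviation is reported.
    max_dev = dev.max(axis=1)
    min_dev = dev.min(axis=1)
    es = np.where(max_dev + 1e-9 >= -min_dev, max_dev, min_dev)
    if np.ndim(hit_mask) == 1:
        return float(es[0]), dev[0]
    return es, dev


def enrichment_score(ranked, gene_set, weight_p: float = 1.0) -> EnrichmentScore:
    """Weighted Kolmogorov-Smirnov enrichment score of one gene set.

    *ranked* is the output of :func:`rank_by_target` (or any DataFrame with
    ``protein``/``score`` columns, a Series of scores indexed by protein, or
    a sequence of ``(protein, score)`` pairs), already in ranking order.
    Hits step the running sum up by |score|^p normalized over hits; misses
    step it down by 1/(N - N_hits); the score is the signed maximum
    deviation, always in [-1, 1] (positive wins when the extrema tie in
    magnitude).  ``weight_p=0`` is the classic unweighted KS form.

    A set with no member in the ranking returns ``es=nan`` (not evaluable);
    a set covering every protein raises.
    """
    if isinstance(ranked, pd.DataFrame):
        ids = ranked["protein"].to_numpy()
        scores = ranked["score"].to_numpy(float)
    elif isinstance(ranked, pd.Series):
        ids = ranked.index.to_numpy()
        scores = ranked.to_numpy(float)
    else:
        ids = np.array([p for p, _ in ranked])
        scores = np.array([s for _, s in ranked], dtype=float)
    members = set(gene_set)
    hit_mask = np.array([p in members for p in ids])
    n_present = int(hit_mask.sum())
    if n_present == 0:
        return EnrichmentScore(float("nan"), np.zeros(len(ids)), np.array([], int), 0)
    if n_present == len(ids):
        raise ValueError("gene set covers every ranked protein")
    es, dev = _es_from_sorted(scores, hit_mask, weight_p)
    return EnrichmentScore(es, dev, np.nonzero(hit_mask)[0], n_present)


def _iter_permutations(n: int, n_perm: int, rng: np.random.Generator):
    """Yield permutation index arrays; exhaustive when n! <= n_perm."""
    if math.factorial(n) <= n_perm:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations of {n} samples; "
            "using the exhaustive set",
            stacklevel=3,
        )
        for perm in itertools.permutations(range(n)):
            yield np.array(perm)
    else:
        for _ in range(n_perm):
            yield rng.permutation(n)


def permutation_test(
    z: pd.DataFrame,
    target,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int | None = 0,
    ranking: str = "pearson",
) -> pd.DataFrame:
    """Phenotype-permutation significance for target-sorted enrichment.

    The null is built by permuting the sample labels of the target vector,
    re-ranking all proteins and recomputing every set's enrichment score.
    For each set, ``NES = ES / mean |null ES of the same sign|`` and
    ``p_perm = (1 + #{same-sign null with |ES_null| >= |ES|}) /
    (n_same_sign + 1)`` (never zero); q-values are Benjamini-Hochberg over
    the evaluable sets.

    Returns a DataFrame with columns ``set, es, nes, p_perm, fdr_q,
    n_members_present`` in the input set order.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    t = _target_vector(z, target)
    zmat = z.to_numpy(float)
    ids = z.index.to_numpy()
    score_fn = _RANKINGS[ranking]

    set_names = list(gene_sets)
    masks = np.zeros((len(set_names), len(ids)), dtype=bool)
    for k, name in enumerate(set_names):
        members = set(gene_sets[name])
        masks[k] = np.isin(ids, list(members))
    n_present = masks.sum(axis=1)
    if (n_present == len(ids)).any():
        bad = [set_names[k] for k in np.nonzero(n_present == len(ids))[0]]
        raise ValueError(f"gene set(s) cover every ranked protein: {bad}")
    evaluable = n_present > 0

    def es_all_sets(tvec: np.ndarray) -> np.ndarray:
        scores = score_fn(zmat, tvec)
        order = np.lexsort((ids, -scores))
        es, _ = _es_from_sorted(scores[order], masks[:, order], weight_p)
        return np.asarray(es)

    obs = es_all_sets(t)
    rng = np.random.default_rng(seed)
    null = np.array([es_all_sets(t[perm]) for perm in _iter_permutations(len(t), n_perm, rng)])

    nes = np.full(len(set_names), np.nan)
    p = np.full(len(set_names), np.nan)
    for k in np.nonzero(evaluable)[0]:
        same = null[:, k][np.sign(null[:, k]) == np.sign(obs[k])]
        p[k] = (1.0 + np.sum(np.abs(same) >= abs(obs[k]))) / (len(same) + 1.0)
        if len(same):
            nes[k] = obs[k] / np.mean(np.abs(same))

    q = np.full(len(set_names), np.nan)
    if evaluable.any():
        q[evaluable] = multipletests(p[evaluable], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "set": set_names,
            "es": np.where(evaluable, obs, np.nan),
            "nes": nes,
            "p_perm": p,
            "fdr_q": q,
            "n_members_present": n_present,
        }
    )


class TargetSortedGSEA(BaseEstimator):
    """Proteotype enrichment estimator: counts + target abundance -> results.

    ``fit(X, y)`` takes a proteins x samples spectral-count matrix (or
    pre-computed z-scores with ``normalize=False``) and the per-sample
    targeted abundance of one drug target, then computes the protein
    ranking, per-set enrichment scores and the permutation null.

    Attributes after fitting: ``zscores_`` (proteins x samples),
    ``ranking_`` (protein, score), ``results_`` (per-set es/nes/p/q).
    """

    def __init__(
        self,
        gene_sets: dict[str, list[str]] | None = None,
        n_perm: int = 1000,
        weight_p: float = 1.0,
        ranking: str = "pearson",
        normalize: bool = True,
        norm_method: str = "median_total",
        random_state: int | None = 0,
    ):
        self.gene_sets = gene_sets
        self.n_perm = n_perm
        self.weight_p = weight_p
        self.ranking = ranking
        self.normalize = normalize
        self.norm_method = norm_method
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "TargetSortedGSEA":
        if not self.gene_sets:
            raise ValueError("gene_sets must be provided")
        self.zscores_ = (
            normalize_counts(X, method=self.norm_method) if self.normalize else X
        )
        self.ranking_ = rank_by_target(self.zscores_, y, ranking=self.ranking)
        self.results_ = permutation_test(
            self.zscores_,
            y,
            self.gene_sets,
            n_perm=self.n_perm,
            weight_p=self.weight_p,
            seed=self.random_state,
            ranking=self.ranking,
        )
        return self

    def score_profile(self, set_name: str) -> EnrichmentScore:
        """Running-sum profile of one gene set on the fitted ranking."""
        check_is_fitted(self, "ranking_")
        return enrichment_score(
            self.ranking_, self.gene_sets[set_name], weight_p=self.weight_p
        )


def plot_enrichment(ranked: pd.DataFrame, gene_set, weight_p: float = 1.0, ax=None):
    """Running-sum enrichment plot: score profile plus member tick marks."""
    import matplotlib.pyplot as plt

    res = enrichment_score(ranked, gene_set, weight_p=weight_p)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(res.running_sum, lw=1.5)
    ax.axhline(0.0, color="grey", lw=0.5)
    ymin = min(res.running_sum.min(), 0)
    for pos in res.hit_positions:
        ax.axvline(pos, ymax=0.08, color="black", lw=0.4)
    ax.set_xlabel("rank by association with target abundance")
    ax.set_ylabel("running enrichment score")
    ax.set_title(f"ES = {res.es:.3f} ({res.n_members_present} members)")
    ax.set_ylim(ymin - 0.05, max(res.running_sum.max(), 0) + 0.05)
    return ax
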