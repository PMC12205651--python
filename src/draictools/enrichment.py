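"""Weighted-KS gene-set enrichment with a permutation null.

Genes are ranked by a signal-to-noise metric between two phenotype groups;
a weighted Kolmogorov–Smirnov running-sum statistic gives the enrichment
score (ES) of a gene set; phenotype-label permutations give a normalized
enrichment score (NES = ES / mean |permutation ES| of the same sign) and a
nominal p-value (fraction of same-sign permutation scores at least as
extreme).  Defaults follow the common GSEA parameterization: weighted
statistic (p = 1), 1000 permutations, gene sets restricted to 10–5000
members after intersection with the expression matrix.

Also provides the quartile stratification (Q1 = lowest, Q4 = highest
quartile of a per-sample quantity) used to contrast isoform-low vs
isoform-high samples, and the row Z-score transform used for heatmap
display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankedList",
    "GeneSet",
    "EnrichmentResult",
    "rank_genes_signal_to_noise",
    "enrichment_score",
    "permutation_nes",
    "stratify_quartiles",
    "row_zscore",
    "bh_qvalues",
]

MIN_SET_SIZE = 10
MAX_SET_SIZE = 5000


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a two-group metric, descending; ties by gene id."""

    genes: tuple[str, ...]
    metric: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate genes")
        m = np.asarray(self.metric)
        if np.any(np.diff(m) > 0):
            raise ValueError("metric must be non-increasing")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with unique members."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        return cls(name=name, members=frozenset(genes))


@dataclass(frozen=True)
class EnrichmentResult:
    """ES, NES and nominal p for one gene set under label permutation."""

    set_name: str
    es: float
    nes: float
    p_nominal: float
    n_perm: int
    seed: int
    set_size: int


class SetSizeError(ValueError):
    """Gene set outside the allowed 10–5000 size window after intersection."""


def _signal_to_noise(
    X: np.ndarray, mask1: np.ndarray
) -> np.ndarray:
    """Vectorized signal-to-noise for one or many group assignments.

    ``X`` is genes x samples; ``mask1`` is (n_assignments, n_samples) boolean
    with True marking the positive class.  Returns (n_assignments, n_genes).
    Per-group standard deviations (ddof=1) are floored at
    max(0.2 * |group mean|, 0.2), the conventional guard against tiny
    variances dominating the ranking.
    """
    mask1 = np.atleast_2d(mask1)
    n1 = mask1.sum(axis=1)
    n0 = (~mask1).sum(axis=1)
    f1 = mask1.astype(float)
    f0 = (~mask1).astype(float)

    s1 = X @ f1.T                      # (genes, assignments)
    s0 = X @ f0.T
    mu1 = s1 / n1
    mu0 = s0 / n0
    sq1 = (X**2) @ f1.T
    sq0 = (X**2) @ f0.T
    var1 = (sq1 - n1 * mu1**2) / (n1 - 1)
    var0 = (sq0 - n0 * mu0**2) / (n0 - 1)
    sd1 = np.sqrt(np.clip(var1, 0.0, None))
    sd0 = np.sqrt(np.clip(var0, 0.0, None))
    sd1 = np.maximum(sd1, np.maximum(0.2 * np.abs(mu1), 0.2))
    sd0 = np.maximum(sd0, np.maximum(0.2 * np.abs(mu0), 0.2))
    return ((mu1 - mu0) / (sd1 + sd0)).T


def rank_genes_signal_to_noise(
    matrix: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    positive_class: str | None = None,
) -> RankedList:
    """Rank genes by signal-to-noise between two phenotype groups.

    ``matrix`` is genes x samples; ``labels`` assigns each sample column to
    one of exactly two classes.  ``positive_class`` names the class whose
    higher expression gives positive metric values (default: the label of
    the first sample column).  Each group must have at least 3 samples.
    """
    labels = pd.Series(labels)
    labels = labels.loc[matrix.columns]
    classes = labels.unique().tolist()
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 phenotype classes, got {classes}")
    if positive_class is None:
        positive_class = labels.iloc[0]
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not in labels")
    counts = labels.value_counts()
    if counts.min() < 3:
        raise ValueError(
            f"each group needs >= 3 samples (got {counts.to_dict()})"
        )

    mask1 = (labels == positive_class).to_numpy()[None, :]
    s2n = _signal_to_noise(matrix.to_numpy(dtype=float), mask1)[0]

    genes = np.array(matrix.index)
    order = np.lexsort((genes, -s2n))   # descending metric, ties by gene id
    return RankedList(
        genes=tuple(genes[order]), metric=tuple(float(x) for x in s2n[order])
    )


def _es_core(
    metric_sorted: np.ndarray, member_sorted: np.ndarray, p_weight: float
) -> tuple[np.ndarray, np.ndarray]:
    """Running sum and ES for pre-sorted metric/membership arrays.

    Both arrays are (n_assignments, n_genes), already ordered by descending
    metric per row.  Returns (running_sums, es) where es is per-assignment.
    """
    w = np.abs(metric_sorted) ** p_weight
    hit = np.where(member_sorted, w, 0.0)
    denom = hit.sum(axis=1, keepdims=True)
    # all-zero member weights: fall back to unweighted hits
    flat = denom[:, 0] == 0
    if np.any(flat):
        hit[flat] = member_sorted[flat].astype(float)
        denom[flat, 0] = hit[flat].sum(axis=1)
    n = member_sorted.shape[1]
    m = member_sorted.sum(axis=1, keepdims=True)
    miss = np.where(member_sorted, 0.0, 1.0 / (n - m))
    running = np.cumsum(hit / denom - miss, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    es = running[np.arange(running.shape[0]), idx]
    return running, es


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, p_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and its running sum.

    The running sum increments by |metric|^p (normalized over set members)
    at member genes and decrements by 1/(N - |S|) elsewhere; ES is the
    signed maximum deviation from zero.
    """
    member = np.array([g in gene_set.members for g in ranked.genes])
    n_inter = int(member.sum())
    if n_inter == 0:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the ranking")
    if n_inter == len(ranked.genes):
        raise ValueError("gene set covers every ranked gene; ES undefined")
    metric = np.asarray(ranked.metric, dtype=float)
    running, es = _es_core(metric[None, :], member[None, :], p_weight)
    return float(es[0]), running[0]


def permutation_nes(
    matrix: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    p_weight: float = 1.0,
    positive_class: str | None = None,
) -> EnrichmentResult:
    """ES, NES and nominal p under phenotype-label permutation.

    Labels are permuted ``n_perm`` times (uniform resampling of label
    orderings, with replacement across permutations).  NES divides the
    observed ES by the mean |permutation ES| of the same sign; the nominal p
    is the fraction of same-sign permutation scores with |ES_perm| >= |ES|,
    floored at 1/(n_perm + 1) so it is never zero.

    Gene sets outside the 10–5000 size window after intersection with the
    matrix raise :class:`SetSizeError`.
    """
    labels = pd.Series(labels).loc[matrix.columns]
    genes = np.array(matrix.index)
    member = np.isin(genes, list(gene_set.members))
    size = int(member.sum())
    if not MIN_SET_SIZE <= size <= MAX_SET_SIZE:
        raise SetSizeError(
            f"gene set {gene_set.name!r} has {size} members after "
            f"intersection; allowed range is {MIN_SET_SIZE}–{MAX_SET_SIZE}"
        )
    if positive_class is None:
        positive_class = labels.iloc[0]
    counts = labels.value_counts()
    if len(counts) != 2 or counts.min() < 3:
        raise ValueError("need two phenotype classes with >= 3 samples each")

    X = matrix.to_numpy(dtype=float)
    obs_mask = (labels == positive_class).to_numpy()

    rng = np.random.default_rng(seed)
    n_samples = X.shape[1]
    perm_masks = np.empty((n_perm, n_samples), dtype=bool)
    for b in range(n_perm):
        perm_masks[b] = obs_mask[rng.permutation(n_samples)]

    all_masks = np.vstack([obs_mask[None, :], perm_masks])
    s2n = _signal_to_noise(X, all_masks)          # (1 + n_perm, genes)

    order = np.lexsort((np.broadcast_to(genes, s2n.shape), -s2n), axis=1)
    rows = np.arange(s2n.shape[0])[:, None]
    metric_sorted = s2n[rows, order]
    member_sorted = member[order]
    _, es_all = _es_core(metric_sorted, member_sorted, p_weight)
    es, es_perm = float(es_all[0]), es_all[1:]

    same_sign = es_perm > 0 if es >= 0 else es_perm < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = float("nan")
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / float(np.mean(np.abs(es_perm[same_sign])))
        p = float(np.mean(np.abs(es_perm[same_sign]) >= abs(es)))
        p = max(p, 1.0 / (n_perm + 1))
    return EnrichmentResult(
        set_name=gene_set.name,
        es=es,
        nes=nes,
        p_nominal=p,
        n_perm=n_perm,
        seed=seed,
        set_size=size,
    )


def stratify_quartiles(
    values: Mapping[str, float] | pd.Series,
) -> tuple[list[str], list[str]]:
    """Split samples into the lowest (Q1) and highest (Q4) quartiles.

    Q1 holds samples at or below the 25th percentile of the values, Q4 those
    at or above the 75th (percentiles by linear interpolation).  Within each
    quartile, membership order is by sample id, making the output
    deterministic under ties.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 4:
        raise ValueError("need at least 4 samples to stratify quartiles")
    if s.nunique() == 1:
        raise ValueError("all values identical; quartile stratification undefined")
    q1_cut = float(np.percentile(s.to_numpy(), 25))
    q4_cut = float(np.percentile(s.to_numpy(), 75))
    q1 = sorted(s.index[s <= q1_cut])
    q4 = sorted(s.index[s >= q4_cut])
    return list(q1), list(q4)


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row standardization (x - row mean) / row sd, sd with n-1 denominator.

    Constant rows map to all-zeros with a warning — they carry no contrast
    but would otherwise divide by zero.
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) set to zero in row Z-score",
            stacklevel=2,
        )
        sd = sd.replace(0.0, np.nan)
    z = matrix.sub(mu, axis=0).div(sd, axis=0)
    return z.fillna(0.0)


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg q-values for a family of nominal p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0.0, 1.0)
    return out
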