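"""Expression-trend clustering and crossbred expression-bias calling.

Implements the time-trend / hybrid-bias track of the pipeline:

* quantile normalization ("correction") of expression toward a common,
  approximately normal reference distribution;
* fuzzy c-means (FCM) clustering of stage-ordered expression trends, the
  Mfuzz-style soft clustering;
* six-pattern trend classification per breed with concordance/discordance
  of each gene's correlation sign against the breed's CSA trajectory;
* t-based confidence intervals of purebred (H, D) expression and the
  classifier of crossbred (HD) expression bias toward either parent breed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "TrendClustering",
    "ConfidenceInterval",
    "BiasCall",
    "quantile_normalize",
    "normalize_to_normal",
    "standardize_rows",
    "fcm_cluster",
    "classify_trend_patterns",
    "TrendPatternResult",
    "confidence_interval",
    "call_bias",
    "aggregate_bias_calls",
    "call_bias_matrix",
    "hypertrophy_gene_screen",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean of the sorted columns.

    Every column ends up with the same sorted values (hence identical
    means); ties within a column receive the average of the reference
    values at their rank positions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(n, dtype=float)
    for j in range(x.shape[1]):
        ranks = scipy.stats.rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples; zero-variance rows become zeros."""
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=matrix.index, columns=matrix.columns)


def normalize_to_normal(
    matrix: pd.DataFrame, standardize: bool = True
) -> pd.DataFrame:
    """Correct skewed (NB-like) expression toward normality.

    Quantile normalization maps every sample onto the common reference
    distribution; with ``standardize`` each gene is additionally z-scored
    across samples (as trend clustering expects).
    """
    corrected = quantile_normalize(matrix)
    return standardize_rows(corrected) if standardize else corrected


@dataclass
class TrendClustering:
    """Fuzzy c-means result: memberships, centers and the objective trace."""

    membership: pd.DataFrame  # genes × clusters, rows sum to 1
    centers: np.ndarray  # clusters × timepoints
    objective_history: list[float]
    n_iter: int
    converged: bool

    def hard_assignment(self) -> pd.Series:
        """Cluster of maximal membership per gene."""
        return pd.Series(
            np.argmax(self.membership.to_numpy(), axis=1),
            index=self.membership.index,
            name="cluster",
        )


def _kmeanspp_init(
    x: np.ndarray, c: int, rng: np.random.Generator
) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(c - 1):
        d2 = np.min(
            ((x[:, None, :] - np.array(centers)[None]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            probs = np.full(len(x), 1.0 / len(x))
        else:
            probs = d2 / total
        centers.append(x[rng.choice(len(x), p=probs)])
    return np.array(centers)


def fcm_cluster(
    trend_matrix: Union[pd.DataFrame, np.ndarray],
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> TrendClustering:
    """Fuzzy c-means clustering of row vectors.

    Minimizes sum_ij u_ij**m * ||x_i - c_j||**2 subject to rows of U
    summing to 1, by the standard alternating updates
    ``u_ij = 1 / sum_k (d_ij / d_ik)**(2/(m-1))`` and membership-weighted
    center means.  A point coinciding with a center gets membership 1 there
    (the usual singularity rule).  Deterministic given ``seed`` (k-means++
    style initialization).
    """
    if isinstance(trend_matrix, pd.DataFrame):
        index = trend_matrix.index
        x = trend_matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(trend_matrix, dtype=float)
        index = pd.RangeIndex(len(x))
    n = len(x)
    if c < 2:
        raise ValueError("c must be >= 2")
    if c > n:
        raise ValueError(f"c = {c} exceeds number of rows ({n})")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(x, c, rng)
    exponent = 1.0 / (m - 1.0)
    u_prev = None
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centers[None]) ** 2).sum(-1)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-exponent)
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            u[rows_zero] = 0.0
            first_zero = np.argmax(zero[rows_zero], axis=1)
            u[np.where(rows_zero)[0], first_zero] = 1.0
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None]) ** 2).sum(-1)
        history.append(float((u**m * d2).sum()))
        if u_prev is not None and np.max(np.abs(u - u_prev)) < tol:
            converged = True
            u_prev = u
            break
        u_prev = u
    membership = pd.DataFrame(
        u_prev, index=index, columns=[f"cluster_{j}" for j in range(c)]
    )
    return TrendClustering(membership, centers, history, n_iter, converged)


@dataclass
class TrendPatternResult:
    """Per-breed trend clusters and cross-breed concordance flags."""

    table: pd.DataFrame  # per gene: cluster_<breed>, sign_<breed>, discordant
    clusterings: dict[str, TrendClustering]
    cluster_signs: dict[str, np.ndarray]


def classify_trend_patterns(
    gene_trends_by_breed: Mapping[str, pd.DataFrame],
    trait_by_breed: Mapping[str, Sequence[float]],
    c: int = 6,
    m: float = 2.0,
    seed: int = 0,
) -> TrendPatternResult:
    """Cluster stage-ordered trends per breed and flag discordant genes.

    Each breed's genes × stages matrix is row-standardized and FCM-clustered
    into ``c`` patterns.  Each cluster's center is correlated with the
    breed's CSA trajectory; a gene inherits its hard cluster's correlation
    sign.  A gene is "discordant" when its sign in the reference breed
    (the first key, conventionally H) differs from its sign in any other
    breed — the signature of genes tracking muscle growth in one breed but
    not its relatives.
    """
    breeds = list(gene_trends_by_breed)
    if len(breeds) < 2:
        raise ValueError("need >= 2 breeds")
    stage_grids = [tuple(df.columns) for df in gene_trends_by_breed.values()]
    if len(set(stage_grids)) != 1:
        raise ValueError("breeds have different stage grids")
    gene_sets = [tuple(df.index) for df in gene_trends_by_breed.values()]
    if len(set(gene_sets)) != 1:
        raise ValueError("breeds have different gene sets")

    clusterings: dict[str, TrendClustering] = {}
    signs: dict[str, np.ndarray] = {}
    columns: dict[str, pd.Series] = {}
    for i, breed in enumerate(breeds):
        trends = standardize_rows(gene_trends_by_breed[breed])
        trait = np.asarray(trait_by_breed[breed], dtype=float)
        if len(trait) != trends.shape[1]:
            raise ValueError(f"trait for {breed} does not match the stage grid")
        clust = fcm_cluster(trends, c=c, m=m, seed=seed + i)
        hard = clust.hard_assignment()
        center_sign = np.zeros(c)
        for j in range(c):
            center = clust.centers[j]
            if np.ptp(center) == 0 or np.ptp(trait) == 0:
                continue
            center_sign[j] = np.sign(np.corrcoef(center, trait)[0, 1])
        clusterings[breed] = clust
        signs[breed] = center_sign
        columns[f"cluster_{breed}"] = hard
        columns[f"sign_{breed}"] = pd.Series(
            center_sign[hard.to_numpy()], index=hard.index
        )
    table = pd.DataFrame(columns)
    ref = breeds[0]
    discordant = pd.Series(False, index=table.index)
    for breed in breeds[1:]:
        discordant |= table[f"sign_{ref}"] != table[f"sign_{breed}"]
    table["discordant"] = discordant
    return TrendPatternResult(table, clusterings, signs)


@dataclass
class ConfidenceInterval:
    """Two-sided t confidence interval: mean ± t_{(1+level)/2, n-1} s/√n."""

    mean: float
    lower: float
    upper: float
    level: float
    n: int

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def confidence_interval(
    values: Sequence[float], level: float = 0.95
) -> ConfidenceInterval:
    """t-based CI of the mean (degenerate width 0 for constant samples)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("confidence interval needs n >= 2")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    half = float(scipy.stats.t.ppf(0.5 + level / 2.0, df=x.size - 1)) * s / np.sqrt(
        x.size
    )
    return ConfidenceInterval(mean, mean - half, mean + half, level, int(x.size))


BiasCallLabel = Literal["toward_D", "toward_H", "unbiased", "ambiguous"]


@dataclass
class BiasCall:
    """One gene × stage bias verdict of crossbred (HD) expression."""

    gene_id: Optional[str]
    stage: Optional[str]
    hd_value: float
    ci_H: ConfidenceInterval
    ci_D: ConfidenceInterval
    call: BiasCallLabel


def _nearest_breed(
    hd: float, mean_h: float, mean_d: float, tie_tol: float
) -> BiasCallLabel:
    dist_h = abs(hd - mean_h)
    dist_d = abs(hd - mean_d)
    scale = max(abs(mean_h), abs(mean_d), 1.0)
    if abs(dist_h - dist_d) <= tie_tol * scale:
        return "ambiguous"
    return "toward_H" if dist_h < dist_d else "toward_D"


def call_bias(
    values_H: Sequence[float],
    values_D: Sequence[float],
    value_HD: Union[float, Sequence[float]],
    level: float = 0.95,
    mode: Literal["two_ci", "pooled_ci"] = "two_ci",
    hd_summary: Literal["mean", "vote"] = "mean",
    gene_id: Optional[str] = None,
    stage: Optional[str] = None,
    tie_tol: float = 1e-9,
) -> BiasCall:
    """Classify crossbred expression relative to the purebred CIs.

    ``two_ci`` (default): HD inside the D interval only → toward_D; inside
    the H interval only → toward_H; inside both → unbiased; inside neither →
    toward the breed with the nearer mean (ambiguous on a tie).
    ``pooled_ci``: one interval from the pooled H+D values; inside →
    unbiased, outside → toward the nearer breed mean.

    ``value_HD`` may be the HD group summary (scalar) or the per-animal
    values; with ``hd_summary="mean"`` the mean is compared, with
    ``"vote"`` each animal is called separately and the majority wins
    (ties → ambiguous).
    """
    vh = np.asarray(values_H, dtype=float)
    vd = np.asarray(values_D, dtype=float)
    if vh.size < 2:
        raise ValueError("group H needs >= 2 values")
    if vd.size < 2:
        raise ValueError("group D needs >= 2 values")
    ci_h = confidence_interval(vh, level)
    ci_d = confidence_interval(vd, level)
    hd_arr = np.atleast_1d(np.asarray(value_HD, dtype=float))

    def call_one(v: float) -> BiasCallLabel:
        if mode == "two_ci":
            in_h = ci_h.contains(v)
            in_d = ci_d.contains(v)
            if in_h and in_d:
                return "unbiased"
            if in_d:
                return "toward_D"
            if in_h:
                return "toward_H"
            return _nearest_breed(v, ci_h.mean, ci_d.mean, tie_tol)
        elif mode == "pooled_ci":
            pooled = confidence_interval(np.concatenate([vh, vd]), level)
            if pooled.contains(v):
                return "unbiased"
            return _nearest_breed(v, ci_h.mean, ci_d.mean, tie_tol)
        raise ValueError(f"unknown mode {mode!r}")

    if hd_summary == "mean" or hd_arr.size == 1:
        hd_value = float(hd_arr.mean())
        verdict = call_one(hd_value)
    elif hd_summary == "vote":
        hd_value = float(hd_arr.mean())
        votes = [call_one(float(v)) for v in hd_arr]
        verdict = _majority(votes)
    else:
        raise ValueError(f"unknown hd_summary {hd_summary!r}")
    return BiasCall(gene_id, stage, hd_value, ci_h, ci_d, verdict)


def _majority(labels: Iterable[BiasCallLabel]) -> BiasCallLabel:
    counts = pd.Series(list(labels)).value_counts()
    top = counts[counts == counts.max()].index
    if len(top) > 1:
        return "ambiguous"
    return str(top[0])


def aggregate_bias_calls(calls: Sequence[BiasCall]) -> BiasCallLabel:
    """A gene's overall bias: majority over its per-stage calls, ties → ambiguous."""
    if not calls:
        raise ValueError("no calls to aggregate")
    return _majority(c.call for c in calls)


def call_bias_matrix(
    corrected: pd.DataFrame,
    sheet,
    genes: Optional[Iterable[str]] = None,
    level: float = 0.95,
    mode: Literal["two_ci", "pooled_ci"] = "two_ci",
    hd_summary: Literal["mean", "vote"] = "mean",
) -> pd.DataFrame:
    """Per-gene, per-stage bias calls over a corrected expression matrix.

    Returns a tidy table (gene_id, stage, call, hd_value, CI bounds) plus
    one ``overall`` row per gene with the majority call across stages.
    """
    t = sheet.table
    stages = [s for s in ("D3", "M3", "M6", "M12") if (t["stage"] == s).any()]
    if genes is None:
        genes = corrected.index
    rows = []
    for gene in genes:
        per_stage = []
        for stg in stages:
            cols_h = sheet.samples_where(breed="H", stage=stg)
            cols_d = sheet.samples_where(breed="D", stage=stg)
            cols_hd = sheet.samples_where(breed="HD", stage=stg)
            if len(cols_h) < 2 or len(cols_d) < 2 or not cols_hd:
                continue
            bc = call_bias(
                corrected.loc[gene, cols_h],
                corrected.loc[gene, cols_d],
                corrected.loc[gene, cols_hd].to_numpy(),
                level=level,
                mode=mode,
                hd_summary=hd_summary,
                gene_id=gene,
                stage=stg,
            )
            per_stage.append(bc)
            rows.append(
                (
                    gene,
                    stg,
                    bc.call,
                    bc.hd_value,
                    bc.ci_H.lower,
                    bc.ci_H.upper,
                    bc.ci_D.lower,
                    bc.ci_D.upper,
                )
            )
        if per_stage:
            rows.append(
                (gene, "overall", aggregate_bias_calls(per_stage), np.nan)
                + (np.nan,) * 4
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "stage",
            "call",
            "hd_value",
            "ci_H_lower",
            "ci_H_upper",
            "ci_D_lower",
            "ci_D_upper",
        ],
    )


def hypertrophy_gene_screen(
    deg_sets: Iterable[Iterable[str]],
    modules: Mapping[str, Iterable[str]],
    module_id: str,
    hubs: Optional[Iterable[str]] = None,
) -> list[str]:
    """Candidate hypertrophy genes: DEG union ∩ module (or hub) genes.

    ``deg_sets`` are the per-stage-pair DEG collections (their union is
    taken), ``modules`` maps module ids to gene collections.  When ``hubs``
    is given the intersection is taken against the module's hub genes
    instead of all members.  Output is sorted for stable downstream use.
    """
    if module_id not in modules:
        raise ValueError(f"unknown module id {module_id!r}")
    degs: set[str] = set()
    for s in deg_sets:
        degs |= set(s)
    target = set(modules[module_id])
    if hubs is not None:
        target &= set(hubs)
    return sorted(degs & target)
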