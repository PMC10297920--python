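"""Weighted co-expression modules, eigengenes and hub-gene screening.

A desk-scale re-implementation of the WGCNA-style workflow: an unsigned
soft-thresholded adjacency ``|cor|**beta``, topological overlap (TOM)
similarity, average-linkage clustering with a static cut, module eigengenes
(first principal component, sign-oriented), eigengene-correlation module
merging, module–trait correlation, and kME/GS hub screening.

Deliberate simplifications versus WGCNA proper: a static tree cut replaces
the dynamic tree cut, and the ``networkScreening`` weight is approximated by
a BH q-value on each gene's trait-correlation test (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform

from .expression import bh_adjust

__all__ = [
    "CoexpressionConfig",
    "CoexpressionModule",
    "HubCriteria",
    "tom_similarity",
    "module_eigengene",
    "build_modules",
    "module_trait_correlation",
    "hub_genes",
    "score_trait_correlation",
]

# WGCNA-style module labels, assigned by decreasing module size
_MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)


@dataclass
class CoexpressionConfig:
    """Parameters of the module-detection pipeline.

    ``merge_height`` follows the usual convention: modules whose eigengenes
    correlate above ``1 - merge_height`` are merged (default 0.25, i.e.
    eigengene correlation > 0.75).  ``cut_height`` is the static cut on the
    TOM dissimilarity dendrogram (which lives in [0, 1]).
    """

    soft_power: float = 6.0
    min_module_size: int = 10
    merge_height: float = 0.25
    cv_min: float = 0.0
    cut_height: float = 0.95

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not (0 < self.merge_height < 1):
            raise ValueError("merge_height must be in (0, 1)")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must be in (0, 1]")
        if self.cv_min < 0:
            raise ValueError("cv_min must be >= 0")


@dataclass
class CoexpressionModule:
    """One co-expression module with its eigengene and member statistics."""

    module_id: str
    gene_ids: list[str]
    eigengene: pd.Series  # per sample, unit variance, sign-oriented
    kme: pd.Series  # per member gene: cor(gene, eigengene)
    module_trait_corr: Optional[tuple[float, float]] = None  # (r, p)

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class HubCriteria:
    """Hub-gene thresholds: kME > kme_min and GS > gs_min.

    ``ns_q_max`` optionally adds the network-screening approximation: the
    BH q-value of the gene–trait correlation test must be <= ns_q_max.
    ``None`` (default) disables it.
    """

    kme_min: float = 0.6
    gs_min: float = 0.8
    ns_q_max: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.gs_min <= 1):
            raise ValueError("gs_min must be in [0, 1]")


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix from an adjacency matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L = A @ A restricted to shared neighbours; diagonal set to 1.
    Symmetric with entries in [0, 1].
    """
    a = np.asarray(adjacency, dtype=float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _eigengene(x: np.ndarray, sample_index: pd.Index) -> pd.Series:
    """First principal component of a genes × samples block.

    Genes are standardized across samples first; the component is scaled to
    unit variance and sign-oriented so that the mean correlation with the
    member genes is positive.
    """
    z = x - x.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]
    # samples × genes SVD; first left singular vector of z.T
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    me = u[:, 0]
    me = me / me.std(ddof=0)
    corrs = np.array([np.corrcoef(me, g)[0, 1] for g in z])
    if np.nanmean(corrs) < 0:
        me = -me
    return pd.Series(me, index=sample_index, name="eigengene")


def module_eigengene(expression_block: pd.DataFrame) -> pd.Series:
    """Eigengene of a gene set: first PC of its genes × samples expression.

    Unit variance, sign-oriented so the mean member correlation is
    positive.  Useful for summarizing an externally defined gene set
    without running module detection.
    """
    return _eigengene(
        expression_block.to_numpy(dtype=float), expression_block.columns
    )


def _label_assignments(sizes: Sequence[int]) -> list[str]:
    labels = list(_MODULE_COLORS) + [
        f"module{i}" for i in range(len(_MODULE_COLORS), len(sizes))
    ]
    return labels[: len(sizes)]


def build_modules(
    expression: pd.DataFrame,
    config: Optional[CoexpressionConfig] = None,
    trait: Optional[pd.Series] = None,
) -> list[CoexpressionModule]:
    """Detect co-expression modules in a genes × samples expression matrix.

    Pipeline: coefficient-of-variation filter, unsigned adjacency
    ``|cor|**beta``, TOM similarity, average-linkage clustering of TOM
    dissimilarity, static cut at ``config.cut_height``, pruning of clusters
    below ``min_module_size`` to the unassigned "grey" module, and iterative
    merging of modules whose eigengenes correlate above
    ``1 - merge_height``.  Modules are labeled by decreasing size with
    WGCNA-style color names; "grey" collects unassigned genes and is
    returned last (without an eigengene-based kME threshold semantic).

    Raises
    ------
    ValueError
        With fewer than 3 samples (correlations would be degenerate).
    """
    if config is None:
        config = CoexpressionConfig()
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate expression profiles")
    x = expression.to_numpy(dtype=float)
    gene_ids = np.array(expression.index)

    keep = np.ones(len(gene_ids), dtype=bool)
    sd = x.std(axis=1, ddof=0)
    keep &= sd > 0
    if config.cv_min > 0:
        mean = x.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
        keep &= cv >= config.cv_min
    grey_genes = list(gene_ids[~keep])
    xk = x[keep]
    ids_k = gene_ids[keep]

    if len(ids_k) < 2:
        raise ValueError("fewer than 2 genes pass the variance/CV filter")

    corr = np.corrcoef(xk)
    adjacency = np.abs(corr) ** config.soft_power
    tom = tom_similarity(adjacency)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    link = sch.linkage(squareform(diss, checks=False), method="average")
    assignment = sch.fcluster(link, t=config.cut_height, criterion="distance")

    clusters: dict[int, np.ndarray] = {}
    for cid in np.unique(assignment):
        members = np.where(assignment == cid)[0]
        if len(members) >= config.min_module_size:
            clusters[cid] = members
        else:
            grey_genes.extend(ids_k[members])

    sample_index = expression.columns

    def eigengenes_of(groups: list[np.ndarray]) -> list[pd.Series]:
        return [_eigengene(xk[m], sample_index) for m in groups]

    groups = list(clusters.values())
    # iterative eigengene merging: modules closer than merge_height collapse
    for _ in range(10):
        if len(groups) < 2:
            break
        mes = eigengenes_of(groups)
        me_mat = np.array([m.to_numpy() for m in mes])
        me_diss = 1.0 - np.corrcoef(me_mat)
        np.fill_diagonal(me_diss, 0.0)
        me_link = sch.linkage(
            squareform(np.clip(me_diss, 0, 2), checks=False), method="average"
        )
        merged = sch.fcluster(me_link, t=config.merge_height, criterion="distance")
        if len(np.unique(merged)) == len(groups):
            break
        new_groups = []
        for mid in np.unique(merged):
            idx = np.where(merged == mid)[0]
            new_groups.append(np.concatenate([groups[i] for i in idx]))
        groups = new_groups

    groups.sort(key=len, reverse=True)
    labels = _label_assignments([len(g) for g in groups])

    modules: list[CoexpressionModule] = []
    for label, members in zip(labels, groups):
        me = _eigengene(xk[members], sample_index)
        kme = pd.Series(
            [float(np.corrcoef(me, xk[m])[0, 1]) for m in members],
            index=ids_k[members],
            name="kME",
        )
        corr_p = None
        if trait is not None:
            corr_p = _pearson(me.to_numpy(), _aligned_trait(trait, sample_index))
        modules.append(
            CoexpressionModule(
                module_id=label,
                gene_ids=list(ids_k[members]),
                eigengene=me,
                kme=kme,
                module_trait_corr=corr_p,
            )
        )
    if grey_genes:
        modules.append(
            CoexpressionModule(
                module_id="grey",
                gene_ids=sorted(map(str, grey_genes)),
                eigengene=pd.Series(np.zeros(len(sample_index)), index=sample_index),
                kme=pd.Series(np.nan, index=sorted(map(str, grey_genes))),
            )
        )
    return modules


def _aligned_trait(trait: pd.Series, sample_index: pd.Index) -> np.ndarray:
    if isinstance(trait, pd.Series):
        missing = set(sample_index) - set(trait.index)
        if missing:
            raise ValueError(f"trait missing samples: {sorted(missing)[:5]}")
        values = trait.loc[sample_index].to_numpy(dtype=float)
    else:
        values = np.asarray(trait, dtype=float)
        if len(values) != len(sample_index):
            raise ValueError("trait length does not match sample count")
    if np.isnan(values).any():
        raise ValueError("trait contains missing values")
    if np.ptp(values) == 0:
        raise ValueError("trait has zero variance")
    return values


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def module_trait_correlation(
    modules: Sequence[CoexpressionModule], trait: pd.Series
) -> pd.DataFrame:
    """Pearson r and two-sided p of each module eigengene against a trait."""
    rows = []
    for mod in modules:
        if mod.module_id == "grey":
            continue
        t = _aligned_trait(trait, mod.eigengene.index)
        r, p = _pearson(mod.eigengene.to_numpy(), t)
        rows.append((mod.module_id, r, p))
    return pd.DataFrame(rows, columns=["module_id", "r", "p"]).set_index("module_id")


def hub_genes(
    module: CoexpressionModule,
    expression: pd.DataFrame,
    trait: pd.Series,
    criteria: Optional[HubCriteria] = None,
) -> list[str]:
    """Members of a module passing the kME/GS hub thresholds.

    kME(g) is the correlation of gene g with the module eigengene, GS(g)
    the absolute correlation with the trait.  With ``criteria.ns_q_max``
    set, genes must additionally have a BH q-value of the GS correlation
    test below that bound (the network-screening approximation).
    """
    if criteria is None:
        criteria = HubCriteria()
    if not module.gene_ids:
        raise ValueError("module is empty")
    t = _aligned_trait(trait, expression.columns)
    me = module.eigengene.to_numpy()
    selected = []
    gs_p = {}
    for g in module.gene_ids:
        xg = expression.loc[g].to_numpy(dtype=float)
        if np.ptp(xg) == 0:
            continue
        kme = float(np.corrcoef(xg, me)[0, 1]) if np.ptp(me) > 0 else 0.0
        r, p = _pearson(xg, t)
        gs = abs(r)
        gs_p[g] = p
        if kme > criteria.kme_min and gs > criteria.gs_min:
            selected.append(g)
    if criteria.ns_q_max is not None and selected:
        genes = list(gs_p)
        q = dict(zip(genes, bh_adjust([gs_p[g] for g in genes])))
        selected = [g for g in selected if q[g] <= criteria.ns_q_max]
    return selected


def score_trait_correlation(
    score_matrix: pd.DataFrame,
    trait: pd.Series,
    method: Literal["spearman", "pearson"] = "spearman",
) -> pd.DataFrame:
    """Row-wise correlation of a score matrix (rows × samples) with a trait.

    Constant rows yield NaN with a note instead of an error.  This is the
    generic replacement for enrichment-score vs trait screens.
    """
    t = _aligned_trait(trait, score_matrix.columns)
    rows = []
    for name, row in score_matrix.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((name, np.nan, np.nan, "constant_row"))
            continue
        if method == "spearman":
            r, p = scipy.stats.spearmanr(x, t)
        elif method == "pearson":
            r, p = scipy.stats.pearsonr(x, t)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((name, float(r), float(p), ""))
    return pd.DataFrame(rows, columns=["row_id", "rho", "p", "note"]).set_index(
        "row_id"
    )
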