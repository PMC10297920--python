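"""Count-matrix normalization, differential expression and enrichment.

Self-contained re-implementations of the standard bulk RNA-seq steps:

* median-of-ratios size factors (depth normalization);
* per-gene negative-binomial Wald tests with method-of-moments dispersion
  estimates shrunk toward a fitted mean–dispersion trend;
* Benjamini–Hochberg correction;
* upper-tail hypergeometric gene-set enrichment.

The NB model is parameterized by mean ``mu`` and dispersion ``alpha`` with
``Var = mu + alpha * mu**2``.  These are deliberate desk-scale equivalents of
the DESeq2-style workflow, not numerical replicas of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BREEDS",
    "STAGES",
    "CountMatrix",
    "SampleSheet",
    "DEResult",
    "EnrichmentResult",
    "size_factors",
    "de_test",
    "bh_adjust",
    "enrich_hypergeometric",
    "stage_specific_degs",
]

BREEDS = ("H", "HD", "D")
STAGES = ("D3", "M3", "M6", "M12")

_LN2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Raw gene × sample counts (rows = genes, columns = samples)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if c.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        values = c.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be nonnegative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        c.index.name = "gene_id"
        c.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class SampleSheet:
    """Sample annotations: breed (H, HD, D), stage (D3..M12), replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "breed", "stage", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sheet")
        bad_breed = set(self.table["breed"]) - set(BREEDS)
        if bad_breed:
            raise ValueError(f"unknown breeds: {sorted(bad_breed)}")
        bad_stage = set(self.table["stage"]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stages: {sorted(bad_stage)}")

    def validate_against(self, counts: CountMatrix) -> None:
        sheet_ids = list(self.table["sample_id"])
        if sorted(sheet_ids) != sorted(counts.sample_ids):
            raise ValueError("sample sheet and count matrix sample ids differ")

    def samples_where(
        self, breed: Optional[str] = None, stage: Optional[str] = None
    ) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if breed is not None:
            mask &= t["breed"] == breed
        if stage is not None:
            mask &= t["stage"] == stage
        return list(t.loc[mask, "sample_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))


def size_factors(counts: Union[CountMatrix, pd.DataFrame]) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample the factor is the median over reference genes (those
    with nonzero counts in every sample) of count/geometric-mean ratios.

    Raises
    ------
    ValueError
        If no gene is nonzero in all samples (advice: filter the matrix).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    k = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    log_geomean = logk.mean(axis=1)
    ref = np.isfinite(log_geomean)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter the matrix "
            "before computing size factors"
        )
    log_ratios = logk[ref] - log_geomean[ref, None]
    log_sf = np.median(log_ratios, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=df.columns, name="size_factor")


@dataclass
class DEResult:
    """Per-gene differential-expression table for one contrast.

    ``log2FoldChange`` is log2(mean_A / mean_B) for contrast ``(A, B)``.
    Genes failing the minimum-count filter have ``tested=False`` and NaN
    statistics; they are excluded from the BH family.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    alpha_used: pd.Series = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05, lfc_min: float = 0.0) -> set[str]:
        """Genes with padj <= alpha and |log2FC| >= lfc_min."""
        t = self.table
        mask = (t["padj"] <= alpha) & (t["log2FoldChange"].abs() >= lfc_min)
        return set(t.index[mask.fillna(False)])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _nb_group_mle(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene NB mean MLE for one group with sample offsets.

    Solves sum_i (k_i - s_i m) / (1 + alpha s_i m) = 0 for m by Newton
    iteration (exact ``sum k / sum s`` when alpha = 0).  Returns the mean
    and the Fisher information of b = log m.  Means are floored at half a
    normalized count so all-zero groups stay finite.
    """
    total_s = s.sum()
    m = k.sum(axis=1) / total_s
    floor = 0.5 / total_s
    m = np.maximum(m, floor)
    for _ in range(n_iter):
        sm = s[None, :] * m[:, None]
        denom = 1.0 + alpha[:, None] * sm
        f = ((k - sm) / denom).sum(axis=1)
        fprime = -(s[None, :] * (1.0 + alpha[:, None] * k) / denom**2).sum(axis=1)
        step = f / fprime
        m_new = np.maximum(m - step, floor)
        if np.max(np.abs(m_new - m) / np.maximum(m, 1e-12)) < 1e-10:
            m = m_new
            break
        m = m_new
    sm = s[None, :] * m[:, None]
    info = (sm / (1.0 + alpha[:, None] * sm)).sum(axis=1)
    return m, info


def _dispersion_mom(
    k: np.ndarray, s: np.ndarray, masks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group method-of-moments dispersion per gene.

    Solves E[(q - qbar)^2] = mu/s + alpha mu^2 on normalized counts
    q = k/s, pooling residual sums of squares over the contrast groups.
    Returns (alpha_hat, mean of normalized counts).
    """
    q = k / s[None, :]
    num = np.zeros(k.shape[0])
    den = np.zeros(k.shape[0])
    for mask in masks:
        n_g = int(mask.sum())
        qg = q[:, mask]
        mu_g = qg.mean(axis=1)
        rss = ((qg - mu_g[:, None]) ** 2).sum(axis=1)
        mean_inv_s = (1.0 / s[mask]).mean()
        num += rss - (n_g - 1) * mu_g * mean_inv_s
        den += (n_g - 1) * mu_g**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(den > 0, num / den, np.nan)
    return alpha_hat, q.mean(axis=1)


def _dispersion_trend(
    alpha_hat: np.ndarray, base_mean: np.ndarray
) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu over genes with positive raw estimates."""
    ok = np.isfinite(alpha_hat) & (alpha_hat > 0) & (base_mean > 0)
    if ok.sum() < 10:
        fallback = np.nanmedian(alpha_hat[alpha_hat > 0]) if ok.any() else 0.1
        return np.full_like(base_mean, max(fallback, 1e-8))
    x = 1.0 / base_mean[ok]
    y = alpha_hat[ok]
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(base_mean, 1e-12)
    return np.clip(trend, 1e-8, 10.0)


def de_test(
    counts: Union[CountMatrix, pd.DataFrame],
    sheet: SampleSheet,
    contrast: tuple[str, str],
    factor: str = "breed",
    stage: Optional[str] = None,
    sf: Optional[pd.Series] = None,
    dispersion_mode: str = "shrunk",
    trend_weight: float = 0.7,
    min_total_count: int = 10,
) -> DEResult:
    """Negative-binomial Wald test between two groups.

    Parameters
    ----------
    contrast:
        ``(group_a, group_b)`` levels of ``factor``; the reported
        ``log2FoldChange`` is log2(mean_a / mean_b).
    factor:
        Sample-sheet column defining the groups ("breed" or "stage").
    stage:
        Optional stage restriction when contrasting breeds.
    dispersion_mode:
        "shrunk" (default): per-gene method-of-moments estimates blended in
        log space with the fitted mean–dispersion trend, weight
        ``trend_weight`` on the trend; "trend": trend only; "gene":
        raw per-gene estimates.
    min_total_count:
        Genes with fewer total counts across the contrast samples are
        excluded from testing and from the BH family.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    t = sheet.table
    sel = t
    if stage is not None:
        sel = sel[sel["stage"] == stage]
    if factor not in sel.columns:
        raise ValueError(f"unknown factor {factor!r}")
    group_a, group_b = contrast
    for g in contrast:
        if not (sel[factor] == g).any():
            raise ValueError(f"contrast group {g!r} absent from sample sheet")
    samples_a = list(sel.loc[sel[factor] == group_a, "sample_id"])
    samples_b = list(sel.loc[sel[factor] == group_b, "sample_id"])
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each contrast group needs >= 2 samples")
    used = samples_a + samples_b
    sub = df[used]
    if sf is None:
        sf = size_factors(sub)
    s = sf.loc[used].to_numpy(dtype=float)
    k = sub.to_numpy(dtype=float)
    mask_a = np.array([c in set(samples_a) for c in used])
    mask_b = ~mask_a

    base_mean = (k / s[None, :]).mean(axis=1)
    tested = k.sum(axis=1) >= min_total_count

    alpha_hat, _ = _dispersion_mom(k, s, [mask_a, mask_b])
    trend = _dispersion_trend(alpha_hat[tested], base_mean[tested])
    alpha_full = np.full(k.shape[0], np.nan)
    if dispersion_mode == "trend":
        alpha_full[tested] = trend
    elif dispersion_mode == "gene":
        alpha_full[tested] = np.clip(alpha_hat[tested], 1e-8, 10.0)
    elif dispersion_mode == "shrunk":
        raw = alpha_hat[tested]
        gene_part = np.log(np.clip(raw, 1e-8, 10.0))
        blended = np.exp(trend_weight * np.log(trend) + (1 - trend_weight) * gene_part)
        # genes with non-positive raw estimates carry no usable signal: trend
        blended = np.where(np.isfinite(raw) & (raw > 0), blended, trend)
        alpha_full[tested] = np.clip(blended, 1e-8, 10.0)
    else:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    n_genes = k.shape[0]
    lfc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    stat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    if tested.any():
        kt = k[tested]
        at = alpha_full[tested]
        m_a, info_a = _nb_group_mle(kt[:, mask_a], s[mask_a], at)
        m_b, info_b = _nb_group_mle(kt[:, mask_b], s[mask_b], at)
        lfc_t = (np.log(m_a) - np.log(m_b)) / _LN2
        se_t = np.sqrt(1.0 / info_a + 1.0 / info_b) / _LN2
        z = lfc_t / se_t
        p_t = 2.0 * scipy.stats.norm.sf(np.abs(z))
        lfc[tested] = lfc_t
        se[tested] = se_t
        stat[tested] = z
        pval[tested] = p_t

    padj = np.full(n_genes, np.nan)
    if tested.any():
        padj[tested] = bh_adjust(pval[tested])

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "tested": tested,
        },
        index=df.index,
    )
    return DEResult(
        table=table,
        contrast=(group_a, group_b),
        alpha_used=pd.Series(alpha_full, index=df.index, name="dispersion"),
    )


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of gene sets in a selection."""

    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        mask = t["padj"].notna() & (t["padj"] < alpha)
        return list(t.index[mask])


def enrich_hypergeometric(
    selected_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of each gene set, BH-corrected.

    Sets are intersected with the universe before testing; sets that become
    empty are reported with a note and excluded from the BH family.  The
    p-value is P[X >= overlap] for X hypergeometric with the universe size,
    the (intersected) set size and the selection size.
    """
    universe = set(universe)
    selected = set(selected_genes)
    if not universe:
        raise ValueError("empty universe")
    if not selected:
        raise ValueError("empty selection")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    m_univ = len(universe)
    n_sel = len(selected)
    rows = []
    for name, genes in gene_sets.items():
        in_univ = set(genes) & universe
        if not in_univ:
            rows.append((name, 0, 0, m_univ, n_sel, np.nan, "empty_after_intersection"))
            continue
        overlap = len(in_univ & selected)
        p = float(scipy.stats.hypergeom.sf(overlap - 1, m_univ, len(in_univ), n_sel))
        rows.append((name, overlap, len(in_univ), m_univ, n_sel, p, ""))
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_set",
            "overlap",
            "set_size",
            "universe_size",
            "selected_size",
            "pvalue",
            "note",
        ],
    ).set_index("gene_set")
    padj = np.full(len(table), np.nan)
    ok = table["pvalue"].notna().to_numpy()
    if ok.any():
        padj[ok] = bh_adjust(table["pvalue"].to_numpy()[ok])
    table["padj"] = padj
    return EnrichmentResult(table)


def stage_specific_degs(
    de_by_stage: Mapping[str, Union[DEResult, Iterable[str]]],
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> dict[str, set[str]]:
    """Genes significant at exactly one stage of a shared contrast.

    Accepts per-stage :class:`DEResult` objects (significance extracted at
    ``alpha``/``lfc_min``; gene universes must match) or pre-computed gene
    collections.  For each stage returns the set of genes significant there
    and at no other stage.
    """
    if len(de_by_stage) < 2:
        raise ValueError("need DE results for >= 2 stages")
    sig: dict[str, set[str]] = {}
    universe: Optional[frozenset] = None
    for st, res in de_by_stage.items():
        if isinstance(res, DEResult):
            u = frozenset(res.table.index)
            if universe is None:
                universe = u
            elif u != universe:
                raise ValueError("inconsistent gene universes across stages")
            sig[st] = res.significant(alpha=alpha, lfc_min=lfc_min)
        else:
            sig[st] = set(res)
    specific: dict[str, set[str]] = {}
    for st in sig:
        others: set[str] = set()
        for other, genes in sig.items():
            if other != st:
                others |= genes
        specific[st] = sig[st] - others
    return specific
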