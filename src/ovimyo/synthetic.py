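"""Synthetic muscle-section images and RNA-seq count matrices with ground truth.

Every downstream stage of the package is exercised against data generated
here, so each generator returns its full ground truth:

* :func:`make_fiber_mosaic` — a boundary-stained (WGA-like) fiber mosaic
  built from a seeded, Lloyd-relaxed Voronoi tessellation, with an exact
  per-fiber interior label map and area table;
* :func:`make_atpase_image` — a dark/light (ATPase-like) mosaic with known
  slow/fast fiber-type labels;
* :func:`make_count_matrix` — negative-binomial counts over a breed × stage
  design with per-sample depth factors, planted differential expression,
  planted co-expression modules and planted crossbred-bias scenarios.

All randomness flows through one ``numpy.random.Generator`` seeded from the
spec; identical specs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import disk
from skimage.segmentation import find_boundaries

from .expression import BREEDS, STAGES, CountMatrix, SampleSheet
from .morphometry import ImageGrid

__all__ = [
    "PackingError",
    "FiberMosaicSpec",
    "ExpressionSimSpec",
    "BIAS_SCENARIOS",
    "make_fiber_mosaic",
    "make_atpase_image",
    "make_count_matrix",
    "make_module_expression",
    "study_design",
]


class PackingError(ValueError):
    """The requested fibers do not fit in the requested image."""


@dataclass
class FiberMosaicSpec:
    """Geometry and rendering parameters of one synthetic fiber mosaic.

    ``area_cv`` is the target coefficient of variation of fiber areas:
    Lloyd relaxation of the Voronoi seeds runs until the realized cell-area
    CV drops to this value (unrelaxed Voronoi sits near 0.55; very small
    targets saturate at the relaxation cap).  ``image_shape=None``
    auto-sizes the canvas so that the mean *interior* fiber area comes out
    close to ``mean_area_px`` after the boundary band is carved out.
    """

    n_fibers: int = 100
    mean_area_px: float = 5000.0
    area_cv: float = 0.25
    boundary_width_px: int = 2
    boundary_intensity: float = 230.0
    interior_intensity: float = 60.0
    noise_sd: float = 8.0
    image_shape: Optional[tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be positive")
        if self.mean_area_px <= 0:
            raise ValueError("mean_area_px must be positive")
        if not (0 <= self.area_cv < 1):
            raise ValueError("area_cv must be in [0, 1)")
        if self.boundary_width_px < 1:
            raise ValueError("boundary_width_px must be a positive integer")
        if not (0 < self.boundary_intensity <= 255):
            raise ValueError("boundary_intensity must be in (0, 255]")
        if not (0 <= self.interior_intensity < 255):
            raise ValueError("interior_intensity must be in [0, 255)")
        if self.boundary_intensity <= self.interior_intensity:
            raise ValueError(
                "boundary_intensity must exceed interior_intensity "
                "(boundary-stained contrast)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def cell_area_px(self) -> float:
        """Voronoi cell area that yields ``mean_area_px`` of interior.

        A squarish cell of side s loses roughly a ``boundary_width_px``-wide
        strip along its perimeter to the boundary band, so we solve
        s**2 - 4*s*w = mean_area_px for s.
        """
        w = self.boundary_width_px
        s = 2.0 * w + np.sqrt(4.0 * w**2 + self.mean_area_px)
        return float(s**2)

    def resolved_shape(self) -> tuple[int, int]:
        if self.image_shape is not None:
            rows, cols = self.image_shape
            if rows < 1 or cols < 1:
                raise ValueError("image_shape entries must be positive")
            if rows * cols < self.n_fibers * self.cell_area_px:
                raise PackingError(
                    f"image {rows}x{cols} cannot hold {self.n_fibers} fibers "
                    f"of mean interior area {self.mean_area_px:.0f} px "
                    f"(need >= {self.n_fibers * self.cell_area_px:.0f} px)"
                )
            return rows, cols
        side = int(np.ceil(np.sqrt(self.n_fibers * self.cell_area_px)))
        side += 2 * self.boundary_width_px  # frame band
        return side, side


def _voronoi_labels(
    shape: tuple[int, int],
    n: int,
    margin: int,
    target_cv: float,
    rng: np.random.Generator,
    max_lloyd: int = 30,
) -> np.ndarray:
    """Full-coverage label map (1..n) from Lloyd-relaxed random seeds.

    Lloyd relaxation (seed -> cell centroid) runs until the cell-area
    coefficient of variation drops to ``target_cv`` or the iteration cap is
    reached: unrelaxed Voronoi cells sit near CV 0.55 and relaxation drives
    the CV down, so the realized CV approaches the target from above (very
    small targets saturate at the cap).
    """
    rows, cols = shape
    seeds = np.column_stack(
        [
            rng.uniform(margin, rows - margin, size=n),
            rng.uniform(margin, cols - margin, size=n),
        ]
    )
    rr, cc = np.mgrid[0:rows, 0:cols]
    pixels = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    labels = None
    for it in range(max_lloyd + 1):
        _, idx = cKDTree(seeds).query(pixels)
        labels = idx.reshape(rows, cols)
        counts = np.bincount(idx, minlength=n).astype(float)
        if (counts == 0).any():
            raise PackingError("a Voronoi cell collapsed; too many fibers")
        if counts.std() / counts.mean() <= target_cv:
            break
        sum_r = np.bincount(idx, weights=pixels[:, 0], minlength=n)
        sum_c = np.bincount(idx, weights=pixels[:, 1], minlength=n)
        seeds = np.column_stack([sum_r / counts, sum_c / counts])
    return labels + 1


def _mosaic_geometry(
    spec: FiberMosaicSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """(interior label map, boundary mask) for a mosaic spec."""
    rows, cols = spec.resolved_shape()
    rng = np.random.default_rng(spec.seed)
    w = spec.boundary_width_px
    labels_full = _voronoi_labels(
        (rows, cols), spec.n_fibers, margin=2 * w, target_cv=spec.area_cv, rng=rng
    )
    boundary = find_boundaries(labels_full, mode="thick")
    if w > 1:
        boundary = ndi.binary_dilation(boundary, structure=disk(w - 1))
    # frame band so no fiber interior touches the image border
    boundary[:w, :] = True
    boundary[-w:, :] = True
    boundary[:, :w] = True
    boundary[:, -w:] = True
    label_map = np.where(boundary, 0, labels_full)
    areas = np.bincount(label_map.ravel(), minlength=spec.n_fibers + 1)[1:]
    if (areas == 0).any():
        raise PackingError(
            "a fiber interior was erased by the boundary band; increase the "
            "image size or mean_area_px"
        )
    return label_map, boundary


def _render(
    interior_values: np.ndarray,
    label_map: np.ndarray,
    boundary: np.ndarray,
    boundary_intensity: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.where(boundary, boundary_intensity, interior_values[label_map])
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _area_table(label_map: np.ndarray) -> pd.DataFrame:
    n = label_map.max()
    areas = np.bincount(label_map.ravel(), minlength=n + 1)[1:]
    rr, cc = np.nonzero(label_map)
    lab = label_map[rr, cc]
    cen_r = np.bincount(lab, weights=rr, minlength=n + 1)[1:] / areas
    cen_c = np.bincount(lab, weights=cc, minlength=n + 1)[1:] / areas
    return pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "area_px": areas.astype(int),
            "centroid_row": cen_r,
            "centroid_col": cen_c,
        }
    )


def make_fiber_mosaic(
    spec: FiberMosaicSpec,
) -> tuple[ImageGrid, np.ndarray, pd.DataFrame]:
    """Render a boundary-stained fiber mosaic with exact ground truth.

    Returns
    -------
    image:
        8-bit :class:`~ovimyo.morphometry.ImageGrid` with dark fiber
        interiors and a bright inter-fiber boundary network.
    label_map:
        Integer array; 0 on the boundary band, fiber label 1..n on
        interiors.  Interior labels partition the non-boundary pixels.
    areas:
        Per-fiber table whose ``area_px`` equals the label-map pixel count
        of that fiber exactly.
    """
    label_map, boundary = _mosaic_geometry(spec)
    # fresh generator stream for rendering noise, decoupled from geometry
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    interiors = np.full(spec.n_fibers + 1, spec.interior_intensity)
    img = _render(
        interiors, label_map, boundary, spec.boundary_intensity, spec.noise_sd, rng
    )
    return ImageGrid(img, bit_depth=8), label_map, _area_table(label_map)


def make_atpase_image(
    proportion_slow: float,
    n_fibers: int = 50,
    seed: int = 0,
    mean_area_px: float = 4000.0,
    area_cv: float = 0.15,
    slow_intensity: float = 50.0,
    fast_intensity: float = 150.0,
    background_intensity: float = 230.0,
    noise_sd: float = 0.0,
) -> tuple[ImageGrid, pd.DataFrame]:
    """Render a dark/light fiber-typing mosaic with known type labels.

    ``round(proportion_slow * n_fibers)`` fibers (ties to even, numpy
    rounding) are labeled slow and rendered dark; the rest are fast and
    grey.  Returns the image and a table (label, fiber_type).  The default
    geometry (mean 4000 px, CV 0.15) keeps every fiber inside the standard
    1400–80 000 px morphometry bounds so typed proportions are exact.
    """
    if not (0.0 <= proportion_slow <= 1.0):
        raise ValueError("proportion_slow must be in [0, 1]")
    spec = FiberMosaicSpec(
        n_fibers=n_fibers,
        mean_area_px=mean_area_px,
        area_cv=area_cv,
        boundary_intensity=background_intensity,
        interior_intensity=min(slow_intensity, fast_intensity),
        noise_sd=noise_sd,
        seed=seed,
    )
    label_map, boundary = _mosaic_geometry(spec)
    n_slow = int(np.round(proportion_slow * n_fibers))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    slow_labels = rng.permutation(n_fibers)[:n_slow] + 1
    is_slow = np.zeros(n_fibers + 1, dtype=bool)
    is_slow[slow_labels] = True
    interiors = np.where(is_slow, slow_intensity, fast_intensity)
    img = _render(
        interiors, label_map, boundary, background_intensity, noise_sd, rng
    )
    types = pd.DataFrame(
        {
            "label": np.arange(1, n_fibers + 1),
            "fiber_type": np.where(is_slow[1:], "slow", "fast"),
        }
    )
    return ImageGrid(img, bit_depth=8), types


# ---------------------------------------------------------------------------
# Expression simulation


BIAS_SCENARIOS = ("toward_D", "toward_H", "intermediate", "unbiased")


def study_design(
    n_h: int = 6, n_hd: int = 5, n_d: int = 3, stages: Sequence[str] = STAGES
) -> list[tuple[str, str, int]]:
    """The breed × stage replicate layout of the study (H 6, HD 5, D 3)."""
    reps = {"H": n_h, "HD": n_hd, "D": n_d}
    return [(b, s, reps[b]) for s in stages for b in BREEDS]


@dataclass
class ExpressionSimSpec:
    """Design of a synthetic NB count matrix with planted structure.

    Counts for gene g in sample s are NB with mean
    ``depth(s) * baseline(g) * 2**effect(g, group(s)) * module_factor(g, s)``
    and variance ``mu + nb_dispersion * mu**2``.  Baselines are log-uniform
    on ``baseline_range``.

    ``planted_de`` maps gene index -> (group_a, group_b, log2fc): group_b
    (a "breed_stage" label) is shifted by 2**log2fc relative to group_a.
    ``planted_modules`` is a list of dicts with keys ``genes`` (indices),
    ``amplitude`` (loading on a per-sample latent profile, default 1)
    and ``noise_sd`` (per-gene-sample log2 noise, default 0.3); the latent
    profiles of different modules are orthogonalized so that planted
    modules are distinct by construction.
    ``planted_bias`` maps gene index -> scenario: the D breed is shifted by
    ``bias_log2fc`` relative to H, and the crossbred HD tracks D
    (``toward_D``), H (``toward_H``), the midpoint (``intermediate``), or no
    breed effect exists at all (``unbiased``).
    All planted gene sets must be pairwise disjoint.
    """

    n_genes: int = 2000
    groups: list[tuple[str, str, int]] = field(default_factory=study_design)
    depth_factors: Optional[Sequence[float]] = None
    nb_dispersion: float = 0.05
    baseline_range: tuple[float, float] = (50.0, 500.0)
    planted_de: Mapping[int, tuple[str, str, float]] = field(default_factory=dict)
    planted_modules: list[dict] = field(default_factory=list)
    planted_bias: Mapping[int, str] = field(default_factory=dict)
    bias_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for breed, stg, n_rep in self.groups:
            if breed not in BREEDS or stg not in STAGES:
                raise ValueError(f"unknown group ({breed}, {stg})")
            if n_rep < 1:
                raise ValueError("replicate counts must be >= 1")
        planted_sets = [set(self.planted_de), set(self.planted_bias)] + [
            set(m["genes"]) for m in self.planted_modules
        ]
        for genes in planted_sets:
            for g in genes:
                if not (0 <= g < self.n_genes):
                    raise ValueError(f"planted gene index {g} out of range")
        for i in range(len(planted_sets)):
            for j in range(i + 1, len(planted_sets)):
                overlap = planted_sets[i] & planted_sets[j]
                if overlap:
                    raise ValueError(
                        f"planted gene sets must be disjoint; shared: {sorted(overlap)[:5]}"
                    )
        if self.planted_bias:
            bad = set(self.planted_bias.values()) - set(BIAS_SCENARIOS)
            if bad:
                raise ValueError(f"unknown bias scenarios: {sorted(bad)}")
            for breed, stg, n_rep in self.groups:
                if n_rep < 2:
                    raise ValueError(
                        f"group ({breed}, {stg}) needs >= 2 replicates for "
                        "confidence intervals on planted bias"
                    )
        if self.depth_factors is not None:
            d = np.asarray(self.depth_factors, dtype=float)
            if len(d) != self.n_samples:
                raise ValueError(
                    f"depth_factors length {len(d)} != {self.n_samples} samples"
                )
            if (d <= 0).any():
                raise ValueError("depth_factors must be positive")

    @property
    def n_samples(self) -> int:
        return sum(n for _, _, n in self.groups)


_BIAS_HD_WEIGHT = {"toward_D": 1.0, "toward_H": 0.0, "intermediate": 0.5}


def _orthogonal_latents(
    rng: np.random.Generator, n_samples: int, n_modules: int
) -> np.ndarray:
    """n_samples × n_modules latent profiles, orthogonal across modules.

    Gaussian draws are QR-orthogonalized and rescaled to unit per-sample
    variance, so distinct planted modules never share a profile by chance.
    """
    if n_modules > n_samples:
        raise ValueError("cannot plant more orthogonal modules than samples")
    raw = rng.normal(0.0, 1.0, size=(n_samples, n_modules))
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # deterministic orientation
    return q * np.sqrt(n_samples)


def make_module_expression(
    n_modules: int = 3,
    genes_per_module: int = 50,
    n_samples: int = 12,
    noise_sd: float = 0.3,
    n_noise_genes: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix with planted co-expression modules plus noise genes.

    Each module's genes follow one of ``n_modules`` orthogonal latent
    per-sample profiles plus N(0, noise_sd) gene-level noise; noise genes
    are pure N(0, 1).  Returns (genes × samples matrix, truth labels:
    ``planted_<k>`` or ``noise``).
    """
    rng = np.random.default_rng(seed)
    latents = _orthogonal_latents(rng, n_samples, n_modules)
    rows, labels = [], []
    for mod in range(n_modules):
        for _ in range(genes_per_module):
            rows.append(latents[:, mod] + rng.normal(0.0, noise_sd, n_samples))
            labels.append(f"planted_{mod}")
    for _ in range(n_noise_genes):
        rows.append(rng.normal(0.0, 1.0, n_samples))
        labels.append("noise")
    index = [f"g{i:04d}" for i in range(len(rows))]
    expr = pd.DataFrame(
        rows, index=index, columns=[f"s{j}" for j in range(n_samples)]
    )
    return expr, pd.Series(labels, index=index, name="module_truth")


def make_count_matrix(
    spec: ExpressionSimSpec,
) -> tuple[CountMatrix, SampleSheet, dict[str, pd.DataFrame]]:
    """Simulate counts with planted effects and return every truth table.

    The truth dict holds ``de`` (gene_id, group_a, group_b, log2fc),
    ``modules`` (gene_id, module), ``bias`` (gene_id, scenario),
    ``baselines`` and ``depth_factors``.
    """
    rng = np.random.default_rng(spec.seed)
    sample_rows = []
    for breed, stg, n_rep in spec.groups:
        for rep in range(1, n_rep + 1):
            sample_rows.append((f"{breed}_{stg}_r{rep}", breed, stg, rep))
    sheet = SampleSheet(
        pd.DataFrame(sample_rows, columns=["sample_id", "breed", "stage", "replicate"])
    )
    sample_ids = list(sheet.table["sample_id"])
    breeds = sheet.table["breed"].to_numpy()
    group_labels = (
        sheet.table["breed"].astype(str) + "_" + sheet.table["stage"].astype(str)
    ).to_numpy()
    n_s = len(sample_ids)
    n_g = spec.n_genes

    depth = (
        np.ones(n_s)
        if spec.depth_factors is None
        else np.asarray(spec.depth_factors, dtype=float)
    )
    lo, hi = spec.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_g))

    log2_effect = np.zeros((n_g, n_s))
    for g, (grp_a, grp_b, lfc) in spec.planted_de.items():
        for grp in (grp_a, grp_b):
            if grp not in set(group_labels):
                raise ValueError(f"planted DE references unknown group {grp!r}")
        log2_effect[g, group_labels == grp_b] += lfc
    for g, scenario in spec.planted_bias.items():
        if scenario == "unbiased":
            continue
        log2_effect[g, breeds == "D"] += spec.bias_log2fc
        log2_effect[g, breeds == "HD"] += _BIAS_HD_WEIGHT[scenario] * spec.bias_log2fc
    if spec.planted_modules:
        latents = _orthogonal_latents(rng, n_s, len(spec.planted_modules))
        for m_idx, module in enumerate(spec.planted_modules):
            genes = np.asarray(sorted(module["genes"]), dtype=int)
            amplitude = float(module.get("amplitude", 1.0))
            noise_sd = float(module.get("noise_sd", 0.3))
            log2_effect[genes] += amplitude * latents[:, m_idx][None, :]
            if noise_sd > 0:
                log2_effect[genes] += rng.normal(0.0, noise_sd, size=(len(genes), n_s))

    mu = depth[None, :] * baselines[:, None] * 2.0**log2_effect
    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    gene_ids = [f"g{i:05d}" for i in range(n_g)]
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))

    de_truth = pd.DataFrame(
        [
            (gene_ids[g], a, b, lfc)
            for g, (a, b, lfc) in sorted(spec.planted_de.items())
        ],
        columns=["gene_id", "group_a", "group_b", "log2fc"],
    )
    module_truth = pd.DataFrame(
        [
            (gene_ids[g], f"planted_{m_idx}")
            for m_idx, module in enumerate(spec.planted_modules)
            for g in sorted(module["genes"])
        ],
        columns=["gene_id", "module"],
    )
    bias_truth = pd.DataFrame(
        [(gene_ids[g], sc) for g, sc in sorted(spec.planted_bias.items())],
        columns=["gene_id", "scenario"],
    )
    truth = {
        "de": de_truth,
        "modules": module_truth,
        "bias": bias_truth,
        "baselines": pd.DataFrame({"gene_id": gene_ids, "baseline": baselines}),
        "depth_factors": pd.DataFrame(
            {"sample_id": sample_ids, "depth_factor": depth}
        ),
    }
    return cm, sheet, truth
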