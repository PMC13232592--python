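"""Pseudobulk negative-binomial Wald differential expression.

The unit of replication is the pseudobulk sample: one individual x one
cell type, with counts summed over that individual's nuclei of the type.
Between-species testing within a cell type and age group follows the
DESeq2 family of models:

* median-of-ratios size factors,
* per-gene NB2 dispersion (variance = mu + alpha * mu^2) by method of
  moments with shrinkage toward a fitted mean-dispersion trend,
* group means fitted by maximum likelihood at fixed dispersion,
* a Wald test on log2(mu_A / mu_B) with standard errors from the
  expected Fisher information,
* Benjamini-Hochberg FDR within each cell type x contrast.

`PseudobulkDE` wraps the pipeline as a model object whose ``fit()``
returns a `DEResults` carrying the per-gene table, the nuisance
estimates and a ``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "PseudobulkMatrix",
    "Contrast",
    "DESet",
    "aggregate_pseudobulk",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "call_de",
    "PseudobulkDE",
    "DEResults",
]

logger = logging.getLogger(__name__)

ALPHA_MIN = 1e-8
META_COLUMNS = ("species", "age_group", "individual", "cell_type")


@dataclass
class PseudobulkMatrix:
    """Genes x samples integer counts with per-sample metadata.

    ``sample_meta`` must carry species, age_group, individual and
    cell_type columns; the (individual, cell_type) pair is the sample
    key and must be unique.
    """

    counts: np.ndarray
    gene_ids: list
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.sample_meta) != self.counts.shape[1]:
            raise ValueError("sample_meta length does not match counts columns")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        key = self.sample_meta[["individual", "cell_type"]].apply(tuple, axis=1)
        if key.duplicated().any():
            dupes = sorted(set(key[key.duplicated()]))
            raise ValueError(f"duplicate (individual, cell_type) samples: {dupes}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, mask) -> "PseudobulkMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return PseudobulkMatrix(
            self.counts[:, idx], list(self.gene_ids),
            self.sample_meta.iloc[idx].reset_index(drop=True),
        )

    def for_cell_type(self, cell_type: str) -> "PseudobulkMatrix":
        return self.subset_samples(
            (self.sample_meta["cell_type"] == cell_type).to_numpy()
        )


@dataclass(frozen=True)
class Contrast:
    """Species A versus species B within one age group (one cell type)."""

    species_a: str
    species_b: str
    age_group: str

    def label(self) -> str:
        return f"{self.species_a}_vs_{self.species_b}_{self.age_group}"


@dataclass(frozen=True)
class DESet:
    """A labeled differential-expression gene set."""

    species_focus: str
    age_group: str
    cell_type: str
    direction: str  # "gain" | "loss"
    genes: frozenset

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain or loss, got {self.direction!r}")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def aggregate_pseudobulk(
    cell_counts,
    cell_meta: pd.DataFrame,
    min_cells: int = 10,
    gene_ids=None,
) -> PseudobulkMatrix:
    """Sum cell-level counts into (individual, cell type) pseudobulk columns.

    Groups with fewer than ``min_cells`` cells are dropped and logged.
    ``cell_counts`` is genes x cells (dense or scipy sparse); ``cell_meta``
    must label every cell with individual, cell_type, species, age_group.
    """
    required = list(META_COLUMNS)
    missing_cols = [c for c in required if c not in cell_meta.columns]
    if missing_cols:
        raise ValueError(f"cell_meta missing columns: {missing_cols}")
    bad = cell_meta[required].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"unlabeled cells at positions {list(np.flatnonzero(bad.to_numpy()))[:20]}"
        )
    if hasattr(cell_counts, "toarray"):
        cell_counts = cell_counts.toarray()
    cell_counts = np.asarray(cell_counts)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(cell_counts.shape[0])]

    meta = cell_meta.reset_index(drop=True)
    cols, col_meta = [], []
    for (ind, ct), idx in meta.groupby(["individual", "cell_type"], sort=True).groups.items():
        idx = np.asarray(list(idx))
        if len(idx) < min_cells:
            logger.info(
                "dropping pseudobulk group (%s, %s): %d < %d cells",
                ind, ct, len(idx), min_cells,
            )
            continue
        cols.append(cell_counts[:, idx].sum(axis=1))
        row = meta.iloc[idx[0]]
        col_meta.append(
            {"species": row["species"], "age_group": row["age_group"],
             "individual": ind, "cell_type": ct, "n_cells": len(idx)}
        )
    if not cols:
        raise ValueError("no pseudobulk group reached min_cells")
    return PseudobulkMatrix(
        np.column_stack(cols).astype(np.int64), list(gene_ids), pd.DataFrame(col_meta)
    )


def size_factors(matrix: PseudobulkMatrix) -> np.ndarray:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Falls back to total-count ratios (with a warning) when no gene is
    expressed in every sample.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    allpos = np.all(counts > 0, axis=1)
    if not allpos.any():
        warnings.warn(
            "no gene expressed in all samples; falling back to total-count ratios",
            stacklevel=2,
        )
        totals = counts.sum(axis=0).astype(float)
        if np.any(totals == 0):
            raise ValueError("sample with zero total counts")
        sf = totals
    else:
        logc = np.log(counts[allpos].astype(float))
        log_geomean = logc.mean(axis=1)
        sf = np.exp(np.median(logc - log_geomean[:, None], axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _group_indices(matrix: PseudobulkMatrix, contrast: Contrast):
    meta = matrix.sample_meta
    in_age = meta["age_group"] == contrast.age_group
    ia = np.flatnonzero(in_age & (meta["species"] == contrast.species_a))
    ib = np.flatnonzero(in_age & (meta["species"] == contrast.species_b))
    return ia, ib


def estimate_dispersion(
    matrix: PseudobulkMatrix,
    size_factors: np.ndarray,
    groups=None,
    shrink: bool = True,
    shrink_weight: float = 0.5,
) -> np.ndarray:
    """Per-gene NB2 dispersion by method of moments on normalized counts.

    The raw estimate for gene g is ``(s2 - m * zbar) / m**2`` where m and
    s2 are the mean and (within-group pooled, df-corrected) variance of
    the normalized counts and ``zbar = mean(1/size_factor)`` accounts for
    the extra Poisson noise normalization introduces. With ``shrink``,
    estimates are pulled halfway (``shrink_weight``) toward a fitted
    mean-dispersion trend ``a0 + a1/m``, which stabilizes the handful of
    samples a pseudobulk contrast offers; the floor is ``ALPHA_MIN``.
    """
    counts = matrix.counts
    if counts.shape[1] < 3:
        raise ValueError("dispersion estimation needs >= 3 samples")
    norm = counts / np.asarray(size_factors)[None, :]
    zbar = float(np.mean(1.0 / np.asarray(size_factors)))

    if groups is None:
        groups = [np.arange(counts.shape[1])]
    m = norm.mean(axis=1)
    # pooled within-group variance with df = n - n_groups
    ss = np.zeros(counts.shape[0])
    df = 0
    for idx in groups:
        idx = np.asarray(idx)
        if idx.size < 2:
            continue
        gm = norm[:, idx].mean(axis=1)
        ss += ((norm[:, idx] - gm[:, None]) ** 2).sum(axis=1)
        df += idx.size - 1
    if df < 1:
        raise ValueError("not enough samples within groups for dispersion")
    s2 = ss / df

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - m * zbar) / np.where(m > 0, m, np.nan) ** 2
    untestable = ~np.isfinite(raw)
    raw = np.where(untestable, ALPHA_MIN, raw)
    if untestable.any():
        logger.info("%d all-zero genes flagged untestable (alpha=ALPHA_MIN)",
                    int(untestable.sum()))

    if not shrink:
        return np.maximum(raw, ALPHA_MIN)

    # trend alpha(m) = a0 + a1/m fitted to informative genes, then a
    # convex blend raw -> trend; negative raw estimates shrink past the
    # trend no further than the floor.
    ok = (m > 0) & ~untestable
    alpha = np.maximum(raw, ALPHA_MIN)
    if ok.sum() >= 10:
        y = np.clip(raw[ok], ALPHA_MIN, None)
        X = np.column_stack([np.ones(ok.sum()), 1.0 / m[ok]])
        keep = np.ones(ok.sum(), bool)
        coef = np.array([np.median(y), 0.0])
        for _ in range(3):  # trimmed refits for robustness to outliers
            coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            fit = X @ coef
            resid = y - fit
            mad = np.median(np.abs(resid - np.median(resid))) + 1e-12
            keep = np.abs(resid) < 5 * 1.4826 * mad
            if keep.sum() < 10:
                keep = np.ones(ok.sum(), bool)
                break
        a0, a1 = max(float(coef[0]), ALPHA_MIN), float(coef[1])
        trend = np.maximum(a0 + a1 / np.where(m > 0, m, 1.0), ALPHA_MIN)
        blended = (1.0 - shrink_weight) * raw + shrink_weight * trend
        alpha = np.maximum(blended, ALPHA_MIN)
        alpha[untestable] = ALPHA_MIN
    return alpha


def _fit_nb_group_mean(counts, sf, alpha, n_iter: int = 100, tol: float = 1e-12):
    """ML normalized mean per gene for one group at fixed dispersion.

    Solves the NB score equation by the fixed-point iteration
    mu <- sum(y) / sum((y + 1/alpha) * alpha * s / (1 + alpha * s * mu)),
    which reduces to the Poisson ML sum(y)/sum(s) as alpha -> 0.
    """
    y = counts.astype(float)
    s = np.asarray(sf, float)[None, :]
    a = np.asarray(alpha, float)[:, None]
    tot = y.sum(axis=1)
    mu = tot / s.sum()
    pos = tot > 0
    for _ in range(n_iter):
        denom = ((y + 1.0 / a) * a * s / (1.0 + a * s * mu[:, None])).sum(axis=1)
        new = np.where(denom > 0, tot / np.where(denom > 0, denom, 1.0), 0.0)
        delta = np.abs(new - mu)
        mu = new
        if np.all(delta[pos] <= tol * np.maximum(mu[pos], 1e-300)):
            break
    return mu


def _expected_info_log(mu, sf, alpha):
    """Expected Fisher information of eta = ln(mu) for one group."""
    s = np.asarray(sf, float)[None, :]
    a = np.asarray(alpha, float)[:, None]
    m = mu[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        info = (s * m / (1.0 + a * s * m)).sum(axis=1)
    return info


def nb_wald_test(
    matrix: PseudobulkMatrix,
    contrast: Contrast,
    size_factors_: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
    mu_floor: float = 0.5,
    shrink_dispersion: bool = True,
) -> pd.DataFrame:
    """NB Wald test of species A vs B within one cell type and age group.

    Returns a per-gene frame with log2fc, se, Wald statistic, two-sided
    normal p and BH-FDR across the genes of this contrast. Genes with an
    all-zero group have their mean floored at ``mu_floor`` normalized
    counts and are flagged; genes zero in both groups get p = 1.
    """
    cts = set(matrix.sample_meta["cell_type"])
    if len(cts) != 1:
        raise ValueError(f"matrix must hold exactly one cell type, got {sorted(cts)}")
    cell_type = next(iter(cts))
    ia, ib = _group_indices(matrix, contrast)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            f"contrast {contrast.label()} needs >= 2 samples per group "
            f"(got {len(ia)}, {len(ib)})"
        )
    sub = matrix.subset_samples(np.concatenate([ia, ib]))
    if size_factors_ is None:
        sf = size_factors(sub)
    else:
        sf = np.asarray(size_factors_, float)[np.concatenate([ia, ib])]
    na = len(ia)
    sfa, sfb = sf[:na], sf[na:]
    ya, yb = sub.counts[:, :na], sub.counts[:, na:]
    if dispersions is None:
        alpha = estimate_dispersion(
            sub, sf, groups=[np.arange(na), np.arange(na, na + len(ib))],
            shrink=shrink_dispersion,
        )
    else:
        alpha = np.asarray(dispersions, float)

    mu_a = _fit_nb_group_mean(ya, sfa, alpha)
    mu_b = _fit_nb_group_mean(yb, sfb, alpha)

    floored_a, floored_b = mu_a < mu_floor, mu_b < mu_floor
    both_zero = (ya.sum(axis=1) == 0) & (yb.sum(axis=1) == 0)
    fa = np.maximum(mu_a, mu_floor)
    fb = np.maximum(mu_b, mu_floor)
    log2fc = np.log2(fa / fb)

    info_a = _expected_info_log(fa, sfa, alpha)
    info_b = _expected_info_log(fb, sfb, alpha)
    ln2 = np.log(2.0)
    se = np.sqrt(1.0 / info_a + 1.0 / info_b) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(stat))
    p[both_zero] = 1.0
    log2fc[both_zero] = 0.0
    flag = np.where(
        both_zero, "untestable",
        np.where(floored_a | floored_b, "floored", ""),
    )
    return pd.DataFrame(
        {
            "gene": list(matrix.gene_ids),
            "cell_type": cell_type,
            "species_a": contrast.species_a,
            "species_b": contrast.species_b,
            "age_group": contrast.age_group,
            "base_mean": (np.concatenate([ya, yb], axis=1) / sf[None, :]).mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "wald_p": np.clip(p, 0.0, 1.0),
            "fdr": bh_fdr(np.clip(p, 0.0, 1.0)),
            "flag": flag,
        }
    )


def call_de(
    calls: pd.DataFrame,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> tuple[DESet, DESet]:
    """Apply the calling rule |log2FC| > threshold (strict), FDR < threshold.

    Returns the (gain, loss) `DESet` pair for the single cell type and
    contrast the calls describe.
    """
    if calls.empty:
        warnings.warn("empty call table: returning empty DE sets", stacklevel=2)
        return (
            DESet("NA", "NA", "NA", "gain", frozenset()),
            DESet("NA", "NA", "NA", "loss", frozenset()),
        )
    for col in ("cell_type", "species_a", "age_group"):
        if calls[col].nunique() != 1:
            raise ValueError(f"call_de expects a single {col}, got {calls[col].unique()}")
    cell_type = calls["cell_type"].iloc[0]
    focal = calls["species_a"].iloc[0]
    age = calls["age_group"].iloc[0]
    sig = calls["fdr"] < fdr_threshold
    gain = frozenset(calls.loc[sig & (calls["log2fc"] > lfc_threshold), "gene"])
    loss = frozenset(calls.loc[sig & (calls["log2fc"] < -lfc_threshold), "gene"])
    return (
        DESet(focal, age, cell_type, "gain", gain),
        DESet(focal, age, cell_type, "loss", loss),
    )


@dataclass
class DEResults:
    """Fitted DE results: per-gene table plus nuisance estimates."""

    frame: pd.DataFrame
    size_factors: np.ndarray
    dispersions: np.ndarray
    contrast: Contrast
    cell_type: str

    def call(self, lfc_threshold: float = 0.5, fdr_threshold: float = 0.05):
        return call_de(self.frame, lfc_threshold, fdr_threshold)

    def summary(self, lfc_threshold: float = 0.5, fdr_threshold: float = 0.05) -> str:
        gain, loss = self.call(lfc_threshold, fdr_threshold)
        top = self.frame.nsmallest(10, "fdr")[
            ["gene", "base_mean", "log2fc", "se", "stat", "wald_p", "fdr"]
        ]
        lines = [
            "Pseudobulk NB Wald differential expression",
            "=" * 58,
            f"cell type:    {self.cell_type}",
            f"contrast:     {self.contrast.label()}",
            f"genes tested: {len(self.frame)}",
            f"dispersion:   median {np.median(self.dispersions):.4g}",
            f"calls at |log2FC| > {lfc_threshold}, FDR < {fdr_threshold}: "
            f"{len(gain)} gains, {len(loss)} losses",
            "",
            "top genes by FDR:",
            top.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)


class PseudobulkDE:
    """NB Wald DE model for one cell type and one species contrast.

    Parameters
    ----------
    matrix : PseudobulkMatrix
        May hold several cell types; ``cell_type`` selects one.
    contrast : Contrast
        Species pair and age group to compare.
    """

    def __init__(
        self,
        matrix: PseudobulkMatrix,
        contrast: Contrast,
        cell_type: str | None = None,
        mu_floor: float = 0.5,
        shrink_dispersion: bool = True,
    ):
        cts = set(matrix.sample_meta["cell_type"])
        if cell_type is None:
            if len(cts) != 1:
                raise ValueError("cell_type required when matrix holds several")
            cell_type = next(iter(cts))
        self.matrix = matrix.for_cell_type(cell_type)
        self.contrast = contrast
        self.cell_type = cell_type
        self.mu_floor = mu_floor
        self.shrink_dispersion = shrink_dispersion

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, sample_meta: pd.DataFrame,
                       contrast: Contrast, **kwargs) -> "PseudobulkDE":
        """Build from a genes x samples DataFrame (index = gene ids)."""
        pm = PseudobulkMatrix(
            counts.to_numpy(), list(counts.index), sample_meta
        )
        return cls(pm, contrast, **kwargs)

    def fit(self) -> DEResults:
        ia, ib = _group_indices(self.matrix, self.contrast)
        sub = self.matrix.subset_samples(np.concatenate([ia, ib]))
        sf = size_factors(sub)
        na = len(ia)
        alpha = estimate_dispersion(
            sub, sf, groups=[np.arange(na), np.arange(na, sub.n_samples)],
            shrink=self.shrink_dispersion,
        )
        frame = nb_wald_test(
            sub, self.contrast, size_factors_=None, dispersions=alpha,
            mu_floor=self.mu_floor,
        )
        return DEResults(frame, sf, alpha, self.contrast, self.cell_type)
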