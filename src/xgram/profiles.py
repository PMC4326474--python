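"""Windowed expression profiles over an ordered gene list.

A transcriptogram assigns to each position ``i`` of the ordered gene
list the average expression over the window of radius ``r`` centred at
``i``, restricted to positions actually measured by the platform
(coverage mask ``theta``):

    value(i) = sum_{j in window(i)} theta_j E_j / sum_{j in window(i)} theta_j

Windows truncate at the list ends; a window with no covered position is
missing (NaN), not zero.  ``r = 0`` recovers the transcriptome itself.

The measured expression of the gene at position ``i`` under condition
``k`` is modelled as three additive (log2-scale) components,

    E = s_ik + b (biological variation, per biological replicate)
            + xi (technical noise, per measurement),

which is what makes the window average useful: with uncorrelated noise
the technical and independent-biology variances shrink like 1/w with
window size w = 2r + 1, while a coherent signal over the window is
preserved.  :func:`decompose_variance` estimates these components from
replicated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet
from .network import GeneOrdering

logger = logging.getLogger(__name__)

__all__ = [
    "Transcriptogram",
    "ClassProfiles",
    "TermProfile",
    "VarianceComponents",
    "boxcar_smooth",
    "boxcar_profile",
    "sample_transcriptograms",
    "class_profiles",
    "relative_profile",
    "project_gene_set",
    "decompose_variance",
]


@dataclass
class Transcriptogram:
    """A windowed expression profile over ordering positions.

    values : per-position window averages, NaN where the window has no
        covered position.
    theta : per-position coverage mask (gene measured by the platform).
    radius : window radius r; window size w = 2r + 1 away from the ends.
    """

    values: np.ndarray
    theta: np.ndarray
    radius: int
    label: str | None = None
    unmapped: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.values)

    def global_mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class ClassProfiles:
    """Per-condition mean transcriptogram with replicate spread.

    ``samples`` holds the per-sample profile matrix (n_samples x N) the
    statistics are computed from (average *after* smoothing).
    """

    condition: str
    mean: np.ndarray
    sd: np.ndarray
    se: np.ndarray
    n_samples: int
    samples: np.ndarray
    sample_ids: list
    radius: int


@dataclass
class TermProfile:
    """Box-car smoothed membership indicator of a gene set."""

    name: str
    indicator: np.ndarray
    profile: np.ndarray
    radius: int
    n_mapped: int


@dataclass
class VarianceComponents:
    """Estimated components of the additive expression model.

    sigma2_xi : per-gene technical variance (across technical
        replicates, pooled within biological replicates).
    sigma2_b : per-gene biological variance (across biological-replicate
        means, with the technical contribution removed, floored at 0).
    kappa_bar : per-position mean off-diagonal covariance of
        biological-replicate means over gene pairs in the window.
    """

    sigma2_xi: pd.Series
    sigma2_b: pd.Series
    kappa_bar: np.ndarray
    radius: int

    @property
    def mean_sigma_xi(self) -> float:
        return float(np.sqrt(self.sigma2_xi.mean()))

    @property
    def mean_sigma_b(self) -> float:
        return float(np.sqrt(self.sigma2_b.mean()))


def window_sizes(n: int, r: int, theta: np.ndarray | None = None) -> np.ndarray:
    """Covered window length per position (2r + 1 at interior, full theta)."""
    if theta is None:
        theta = np.ones(n, dtype=bool)
    ccnt = np.concatenate([[0], np.cumsum(np.asarray(theta, dtype=np.int64))])
    idx = np.arange(n)
    lo = np.maximum(0, idx - r)
    hi = np.minimum(n - 1, idx + r)
    return ccnt[hi + 1] - ccnt[lo]


def boxcar_smooth(x: np.ndarray, theta: np.ndarray, r: int) -> np.ndarray:
    """Truncated box-car average of ``x`` under coverage mask ``theta``.

    Linear in ``x`` for fixed theta; O(N) via cumulative sums.
    """
    if r < 0:
        raise ValueError("radius must be >= 0")
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=bool)
    n = len(x)
    xv = np.where(theta, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(xv)])
    ccnt = np.concatenate([[0], np.cumsum(theta.astype(np.int64))])
    idx = np.arange(n)
    lo = np.maximum(0, idx - r)
    hi = np.minimum(n - 1, idx + r)
    num = csum[hi + 1] - csum[lo]
    den = (ccnt[hi + 1] - ccnt[lo]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def _align_to_ordering(
    values: pd.Series, ordering: GeneOrdering
) -> tuple[np.ndarray, np.ndarray, list]:
    """Place gene-keyed values onto ordering positions.

    Returns (per-position values, theta mask, unmapped gene list).
    Duplicated gene labels must have been collapsed upstream.
    """
    n = ordering.n
    x = np.full(n, np.nan)
    theta = np.zeros(n, dtype=bool)
    unmapped = []
    pos = ordering.positions
    for gene, val in values.items():
        p = pos.get(gene)
        if p is None:
            unmapped.append(gene)
        else:
            x[p] = val
            theta[p] = True
    return x, theta, unmapped


def boxcar_profile(
    expression_column: pd.Series,
    ordering: GeneOrdering,
    r: int,
    label: str | None = None,
) -> Transcriptogram:
    """Transcriptogram of one sample.

    Genes absent from the ordering are dropped (kept in ``unmapped``
    with a logged count); ordering positions without a measured gene
    get theta = 0 and are averaged over by their covered neighbours.
    """
    x, theta, unmapped = _align_to_ordering(expression_column, ordering)
    if not theta.any():
        raise ValueError("no overlap between expression genes and the ordering")
    if unmapped:
        logger.info(
            "%d gene(s) not in the ordering dropped from profile", len(unmapped)
        )
    values = boxcar_smooth(x, theta, r)
    return Transcriptogram(
        values=values, theta=theta, radius=r, label=label, unmapped=unmapped
    )


def sample_transcriptograms(
    expression: pd.DataFrame, ordering: GeneOrdering, r: int
) -> tuple[np.ndarray, np.ndarray, list]:
    """Profiles for every sample column: (n_samples x N matrix, theta, unmapped)."""
    mat = np.empty((expression.shape[1], ordering.n))
    theta = None
    unmapped: list = []
    for j, col in enumerate(expression.columns):
        tg = boxcar_profile(expression[col], ordering, r, label=str(col))
        mat[j] = tg.values
        theta = tg.theta
        unmapped = tg.unmapped
    return mat, theta, unmapped


def _samples_of(design: pd.DataFrame, condition: str) -> pd.DataFrame:
    sub = design[design["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not present in design")
    return sub


def class_profiles(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    ordering: GeneOrdering,
    r: int,
    conditions: list | None = None,
) -> dict[str, ClassProfiles]:
    """Mean transcriptogram, SD and SE per condition.

    Each sample is smoothed first, then the class statistics are taken
    over the sample profiles (average after smoothing), so coverage
    gaps are handled per sample.
    """
    missing = [s for s in design["sample"] if s not in expression.columns]
    if missing:
        raise ValueError(f"design sample(s) missing from expression: {missing[:3]}")
    conditions = conditions or list(dict.fromkeys(design["condition"]))
    out = {}
    for cond in conditions:
        sub = _samples_of(design, cond)
        cols = list(sub["sample"])
        mat, _, _ = sample_transcriptograms(expression[cols], ordering, r)
        n = len(cols)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1) if n > 1 else np.zeros(mat.shape[1])
        out[cond] = ClassProfiles(
            condition=cond,
            mean=mean,
            sd=sd,
            se=sd / np.sqrt(n),
            n_samples=n,
            samples=mat,
            sample_ids=cols,
            radius=r,
        )
    return out


def relative_profile(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    ordering: GeneOrdering,
    r: int,
    reference: str,
    conditions: list | None = None,
) -> pd.DataFrame:
    """Relative average transcriptograms against a reference class.

    For each biological replicate: the mean over its technical
    replicates divided, position-wise, by the mean over all
    transcriptograms of the reference condition.  The reference class
    relative to itself averages to 1.  Non-positive reference values
    yield missing (NaN) at that position rather than an error.

    Returns a DataFrame with one row per (condition, bio_rep) and one
    column per ordering position.
    """
    ref_sub = _samples_of(design, reference)
    ref_mat, _, _ = sample_transcriptograms(
        expression[list(ref_sub["sample"])], ordering, r
    )
    ref_mean = np.nanmean(ref_mat, axis=0)
    ref_mean = np.where(ref_mean > 0, ref_mean, np.nan)

    conditions = conditions or list(dict.fromkeys(design["condition"]))
    rows = {}
    for cond in conditions:
        sub = _samples_of(design, cond)
        for b, grp in sub.groupby("bio_rep"):
            mat, _, _ = sample_transcriptograms(
                expression[list(grp["sample"])], ordering, r
            )
            with np.errstate(invalid="ignore"):
                rows[(cond, int(b))] = np.nanmean(mat, axis=0) / ref_mean
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["condition", "bio_rep"])
    return out


def project_gene_set(
    gene_set: GeneSet, ordering: GeneOrdering, r: int
) -> TermProfile:
    """Smoothed membership profile of a gene set along the ordering.

    Assigns 1 to positions whose gene belongs to the set, 0 otherwise,
    then applies the same truncated box-car (full coverage).  Peaks
    mark intervals of the list enriched with the set's genes.
    """
    n = ordering.n
    indicator = np.zeros(n)
    n_mapped = 0
    for g in gene_set.members:
        p = ordering.positions.get(g)
        if p is not None:
            indicator[p] = 1.0
            n_mapped += 1
    if n_mapped == 0:
        logger.info("gene set %r has no overlap with the ordering", gene_set.name)
    profile = boxcar_smooth(indicator, np.ones(n, dtype=bool), r)
    return TermProfile(
        name=gene_set.name,
        indicator=indicator,
        profile=profile,
        radius=r,
        n_mapped=n_mapped,
    )


def decompose_variance(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    ordering: GeneOrdering,
    r: int,
) -> VarianceComponents:
    """Estimate technical and biological variance components per gene.

    sigma2_xi pools, within each (condition, biological replicate)
    cell, the sample variance across technical replicates.  sigma2_b is
    the variance across biological-replicate means minus the technical
    share sigma2_xi / n_a, floored at zero.  kappa_bar is, per window,
    the mean covariance of biological-replicate means over distinct
    gene pairs: ~0 when biology varies independently gene by gene, and
    ~sigma2_b when whole windows move coherently.
    """
    genes = expression.index
    conds = list(dict.fromkeys(design["condition"]))

    xi_num = pd.Series(0.0, index=genes)
    xi_den = 0
    b_acc = []
    kappa_acc = []

    for cond in conds:
        sub = _samples_of(design, cond)
        bio_means = {}
        for b, grp in sub.groupby("bio_rep"):
            cols = list(grp["sample"])
            vals = expression[cols]
            if len(cols) >= 2:
                xi_num += vals.var(axis=1, ddof=1) * (len(cols) - 1)
                xi_den += len(cols) - 1
            bio_means[b] = vals.mean(axis=1)
        if len(bio_means) >= 2:
            bm = pd.DataFrame(bio_means)  # genes x n_b
            b_acc.append((bm, sub.groupby("bio_rep").size().min()))

    if xi_den == 0:
        raise ValueError(
            "sigma2_xi needs >= 2 technical replicates within some biological replicate"
        )
    sigma2_xi = xi_num / xi_den
    if not b_acc:
        raise ValueError("sigma2_b needs >= 2 biological replicates in some condition")

    sigma2_b_parts = []
    for bm, n_a in b_acc:
        raw = bm.var(axis=1, ddof=1) - sigma2_xi / n_a
        sigma2_b_parts.append(raw)
    sigma2_b = pd.concat(sigma2_b_parts, axis=1).mean(axis=1).clip(lower=0.0)

    # window-mean off-diagonal covariance of biological-replicate means
    for bm, _ in b_acc:
        kappa_acc.append(_window_offdiag_cov(bm, ordering, r))
    kappa_bar = np.nanmean(np.vstack(kappa_acc), axis=0)

    return VarianceComponents(
        sigma2_xi=sigma2_xi, sigma2_b=sigma2_b, kappa_bar=kappa_bar, radius=r
    )


def _window_offdiag_cov(
    bio_means: pd.DataFrame, ordering: GeneOrdering, r: int
) -> np.ndarray:
    """Mean off-diagonal covariance (across bio reps) per window.

    Uses cov(sum) = sum of all covariances: the mean over distinct
    pairs is (var(window sum) - sum of per-gene vars) / (w (w - 1)),
    computed with sliding sums so the whole profile is O(N * n_b).
    """
    n = ordering.n
    n_b = bio_means.shape[1]
    centered = bio_means.sub(bio_means.mean(axis=1), axis=0)  # genes x n_b
    # per-position matrices
    c = np.full((n, n_b), np.nan)
    theta = np.zeros(n, dtype=bool)
    for gene, row in centered.iterrows():
        p = ordering.positions.get(gene)
        if p is not None:
            c[p] = row.to_numpy()
            theta[p] = True
    var_g = np.where(theta, np.nansum(c**2, axis=1) / (n_b - 1), 0.0)
    cz = np.where(theta[:, None], c, 0.0)
    idx = np.arange(n)
    lo = np.maximum(0, idx - r)
    hi = np.minimum(n - 1, idx + r)
    csum = np.concatenate([np.zeros((1, n_b)), np.cumsum(cz, axis=0)])
    vsum = np.concatenate([[0.0], np.cumsum(var_g)])
    wcnt = np.concatenate([[0], np.cumsum(theta.astype(np.int64))])
    s = csum[hi + 1] - csum[lo]  # window sum of centered bio means, per rep
    w = (wcnt[hi + 1] - wcnt[lo]).astype(float)
    var_sum = np.sum(s**2, axis=1) / (n_b - 1)
    tot_var = vsum[hi + 1] - vsum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(w >= 2, (var_sum - tot_var) / (w * (w - 1)), np.nan)
    return out
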