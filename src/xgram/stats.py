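"""Per-position differential expression, noise and concordance statistics.

Differences between conditions are tested position by position on the
transcriptogram values with Welch's two-tailed t-test; the family of
tests (one per ordering position) is controlled by Bonferroni at a
family level (default 0.01) and by FDR (Benjamini-Hochberg and a
Storey-style q-value with smoothed pi0).

Class-level diagnostics follow the signal model: the contrast ``C_i``
is the deviation of a class mean transcriptogram from its own global
average, the noise is the replicate SD per position, and their
position-averaged ratio ``omega`` (contrast-to-noise) quantifies how
much signal a window size preserves relative to the noise it removes.
Cross-laboratory agreement of per-position fold changes is measured by
Lin's concordance correlation coefficient

    rho_c = 2 s12 / (s1^2 + s2^2 + (mu1 - mu2)^2)

with population (1/n) moments, which penalises location and scale
shifts that Pearson correlation ignores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import GeneOrdering
from .profiles import class_profiles, sample_transcriptograms

__all__ = [
    "ComparisonResults",
    "NoiseReport",
    "ConcordanceResult",
    "welch_compare",
    "estimate_fdr",
    "contrast_noise",
    "concordance",
    "reproducibility_curve",
    "DifferentialTranscriptogram",
]


@dataclass
class ComparisonResults:
    """Per-position differential-expression results.

    ``frame`` columns: mean_a, mean_b, diff, z (effect size: mean
    difference over the pooled standard error), t, df, p, bonferroni
    (significance flag), q_bh, q_storey.  ``summary()`` renders a
    compact report.
    """

    frame: pd.DataFrame
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    radius: int | None
    family_alpha: float
    family_size: int
    pi0: float

    @property
    def bonferroni_threshold(self) -> float:
        return self.family_alpha / self.family_size

    def n_significant(self, level: str = "bonferroni") -> int:
        if level == "bonferroni":
            return int(self.frame["bonferroni"].sum())
        return int((self.frame[level] < self.family_alpha).sum())

    def fdr_at(self, p_cut: float, method: str = "storey") -> float:
        """Estimated FDR among positions called at P < p_cut."""
        col = "q_storey" if method == "storey" else "q_bh"
        mask = self.frame["p"] < p_cut
        if not mask.any():
            return float("nan")
        return float(self.frame.loc[mask, col].max())

    def summary(self) -> str:
        f = self.frame
        lines = [
            f"Transcriptogram comparison: {self.group_a} vs {self.group_b}",
            "=" * 58,
            f"replicate profiles    : {self.n_a} vs {self.n_b}",
            f"window radius r       : {self.radius}",
            f"positions tested      : {int(f['p'].notna().sum())} of {len(f)}",
            f"family alpha          : {self.family_alpha}"
            f"  (Bonferroni P < {self.bonferroni_threshold:.3g})",
            f"Bonferroni significant: {self.n_significant()}",
            f"P < 0.01 positions    : {int((f['p'] < 0.01).sum())}",
            f"Storey pi0            : {self.pi0:.3f}",
            f"min P                 : {np.nanmin(f['p'].to_numpy()):.3g}",
        ]
        return "\n".join(lines)


@dataclass
class NoiseReport:
    """Contrast / noise diagnostics for one class at one radius."""

    condition: str
    radius: int
    contrast: np.ndarray  # C_i per position
    sd: np.ndarray  # sigma_i per position
    omega_avg: float  # average noise Omega(r)
    cnr: float  # contrast-to-noise omega
    snr: float  # signal-to-noise
    per_position: bool = False


@dataclass
class ConcordanceResult:
    """Lin's concordance between two aligned fold-change vectors."""

    rho_c: float
    pearson: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    sigma12: float
    n: int


def _welch_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorised Welch t, Satterthwaite df and two-tailed P per column.

    NaN entries are ignored per position; positions with fewer than two
    finite values in either group come back NaN.  If both groups have
    zero variance the convention is t = 0, P = 1 for equal means and
    P = 0 (t = +-inf) for unequal means.
    """
    n1 = np.sum(np.isfinite(a), axis=0).astype(float)
    n2 = np.sum(np.isfinite(b), axis=0).astype(float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=0)
        m2 = np.nanmean(b, axis=0)
        v1 = np.nanvar(a, axis=0, ddof=1)
        v2 = np.nanvar(b, axis=0, ddof=1)
        se2 = v1 / n1 + v2 / n2
        diff = m1 - m2
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        # degenerate: both variances zero
        degen = ok & (se2 == 0)
        t = np.where(degen & (diff == 0), 0.0, t)
        t = np.where(degen & (diff != 0), np.sign(diff) * np.inf, t)
    df = np.where(degen, n1 + n2 - 2, df)
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(degen & (diff == 0), 1.0, p)
    p = np.where(degen & (diff != 0), 0.0, p)
    t = np.where(ok, t, np.nan)
    df = np.where(ok, df, np.nan)
    p = np.where(ok, p, np.nan)
    return m1, m2, t, df, p, se2


def welch_compare(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    family_alpha: float = 0.01,
    family_size: int | None = None,
    group_a: str = "A",
    group_b: str = "B",
    radius: int | None = None,
) -> ComparisonResults:
    """Position-wise Welch two-tailed t-test between two replicate sets.

    ``profiles_a``/``profiles_b`` are (replicates x positions) matrices
    of transcriptogram values; every sample profile counts as one
    replicate.  The Bonferroni family size defaults to the number of
    non-missing tested positions; pass ``family_size`` to use the full
    ordering length instead (the convention used when coverage is
    complete).
    """
    a = np.atleast_2d(np.asarray(profiles_a, dtype=float))
    b = np.atleast_2d(np.asarray(profiles_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 replicate profiles")
    if a.shape[1] != b.shape[1]:
        raise ValueError("profile matrices have different numbers of positions")
    m1, m2, t, df, p, se2 = _welch_arrays(a, b)
    tested = int(np.isfinite(p).sum())
    if tested == 0:
        raise ValueError("no position has enough replicates to test")
    m = family_size if family_size is not None else tested
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m1 - m2) / np.sqrt(se2)
    q_bh = estimate_fdr(p, method="bh")
    q_st, pi0 = estimate_fdr(p, method="storey")
    frame = pd.DataFrame(
        {
            "mean_a": m1,
            "mean_b": m2,
            "diff": m1 - m2,
            "z": z,
            "t": t,
            "df": df,
            "p": p,
            "bonferroni": p < family_alpha / m,
            "q_bh": q_bh,
            "q_storey": q_st,
        }
    )
    return ComparisonResults(
        frame=frame,
        group_a=group_a,
        group_b=group_b,
        n_a=a.shape[0],
        n_b=b.shape[0],
        radius=radius,
        family_alpha=family_alpha,
        family_size=m,
        pi0=pi0,
    )


def estimate_fdr(p_values, method: str = "bh", lambdas=None):
    """q-values from raw P-values.

    ``bh`` is Benjamini-Hochberg.  ``storey`` multiplies the BH
    quantity by an estimate of pi0, the null proportion, obtained from
    the tail counts #{p > lambda} / (m (1 - lambda)) smoothed by a
    cubic polynomial over a lambda grid and evaluated at the largest
    lambda.  Returns q (bh) or (q, pi0) (storey).  NaN P-values pass
    through as NaN q-values.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    pf = p[finite]
    if pf.size and (pf.min() < 0 or pf.max() > 1):
        raise ValueError("P-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if pf.size:
        q[finite] = multipletests(pf, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method != "storey":
        raise ValueError(f"unknown FDR method {method!r}")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    m = pf.size
    if m == 0:
        return q, float("nan")
    pi0_raw = np.array([np.mean(pf > lam) / (1.0 - lam) for lam in lambdas])
    if len(lambdas) >= 4:
        coeffs = np.polyfit(lambdas, pi0_raw, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    else:
        pi0 = float(pi0_raw[-1])
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    q_storey = np.minimum(q * pi0, 1.0)
    return q_storey, pi0


def contrast_noise(
    profiles: np.ndarray,
    condition: str = "",
    radius: int = 0,
    per_position: bool = False,
) -> NoiseReport:
    """Contrast, noise and their ratios for one class of replicates.

    C_i = |class mean at i - class global average|; sigma_i = SD of the
    replicate profiles at i; Omega = position-average of sigma_i;
    omega (CNR) = position-average of C_i over Omega; SNR =
    position-average of the class mean over Omega.  With
    ``per_position=True`` the ratios are averaged per position instead
    (mean of C_i / sigma_i).  Zero noise everywhere yields inf ratios
    rather than an error.
    """
    mat = np.atleast_2d(np.asarray(profiles, dtype=float))
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 replicate profiles")
    mean = np.nanmean(mat, axis=0)
    global_avg = np.nanmean(mean)
    c = np.abs(mean - global_avg)
    sd = np.nanstd(mat, axis=0, ddof=1)
    omega_avg = float(np.nanmean(sd))
    with np.errstate(divide="ignore", invalid="ignore"):
        if per_position:
            cnr = float(np.nanmean(c / sd))
            snr = float(np.nanmean(mean / sd))
        else:
            cnr = float(np.nanmean(c) / omega_avg) if omega_avg >= 0 else np.nan
            snr = float(np.nanmean(mean) / omega_avg)
    return NoiseReport(
        condition=condition,
        radius=radius,
        contrast=c,
        sd=sd,
        omega_avg=omega_avg,
        cnr=cnr,
        snr=snr,
        per_position=per_position,
    )


def concordance(fc_lab1, fc_lab2) -> ConcordanceResult:
    """Lin's concordance correlation between two aligned vectors.

    Uses population (1/n) moments.  Positions missing in either vector
    are dropped pairwise.
    """
    x = np.asarray(fc_lab1, dtype=float)
    y = np.asarray(fc_lab2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 aligned finite entries")
    mu1, mu2 = float(x.mean()), float(y.mean())
    s1 = float(np.mean((x - mu1) ** 2))
    s2 = float(np.mean((y - mu2) ** 2))
    s12 = float(np.mean((x - mu1) * (y - mu2)))
    denom = s1 + s2 + (mu1 - mu2) ** 2
    rho_c = 2.0 * s12 / denom if denom > 0 else float("nan")
    pear = s12 / np.sqrt(s1 * s2) if s1 > 0 and s2 > 0 else float("nan")
    return ConcordanceResult(
        rho_c=rho_c,
        pearson=pear,
        mu1=mu1,
        mu2=mu2,
        sigma1=float(np.sqrt(s1)),
        sigma2=float(np.sqrt(s2)),
        sigma12=s12,
        n=n,
    )


def _fold_change(
    expression: pd.DataFrame,
    design: pd.DataFrame,
    ordering: GeneOrdering,
    r: int,
    cond_a: str,
    cond_b: str,
) -> np.ndarray:
    """Per-position log2 fold change A vs B on transcriptogram values."""
    cp = class_profiles(expression, design, ordering, r, conditions=[cond_a, cond_b])
    return cp[cond_a].mean - cp[cond_b].mean


def reproducibility_curve(
    expr_lab1: pd.DataFrame,
    expr_lab2: pd.DataFrame,
    design: pd.DataFrame,
    ordering: GeneOrdering,
    radii,
    conditions: tuple[str, str] | None = None,
    random_seed: int = 0,
) -> pd.DataFrame:
    """Cross-laboratory concordance rho_c versus window radius.

    Both laboratories must have measured the same two conditions under
    the shared design.  For each radius (r = 0 is the plain
    transcriptome) the per-position fold change between the two
    conditions is computed in each laboratory on transcriptogram
    values and their concordance taken; the same computation on a
    seeded random permutation of the ordering provides the baseline in
    which functional neighbourhoods are destroyed.
    """
    conds = list(dict.fromkeys(design["condition"]))
    if conditions is None:
        if len(conds) != 2:
            raise ValueError("design must contain exactly two conditions")
        conditions = (conds[0], conds[1])
    for c in conditions:
        if c not in conds:
            raise ValueError(f"condition {c!r} not present in design")
    rng = np.random.default_rng(random_seed)
    shuffled = list(ordering.order)
    rng.shuffle(shuffled)
    random_ordering = GeneOrdering(shuffled)
    rows = []
    for r in radii:
        fc1 = _fold_change(expr_lab1, design, ordering, r, *conditions)
        fc2 = _fold_change(expr_lab2, design, ordering, r, *conditions)
        cc = concordance(fc1, fc2)
        fc1r = _fold_change(expr_lab1, design, random_ordering, r, *conditions)
        fc2r = _fold_change(expr_lab2, design, random_ordering, r, *conditions)
        ccr = concordance(fc1r, fc2r)
        rows.append(
            {
                "r": r,
                "rho_c": cc.rho_c,
                "pearson": cc.pearson,
                "rho_c_random": ccr.rho_c,
            }
        )
    return pd.DataFrame(rows)


class DifferentialTranscriptogram:
    """Model: per-position differential expression on transcriptograms.

    Built from an expression matrix, its design table, a gene ordering
    and a window radius; ``fit`` smooths every sample, runs the Welch
    test per position between two conditions and attaches multiplicity
    control.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        design: pd.DataFrame,
        ordering: GeneOrdering,
        radius: int,
    ):
        self.expression = expression
        self.design = design
        self.ordering = ordering
        self.radius = radius

    def fit(
        self,
        group_a: str,
        group_b: str,
        family_alpha: float = 0.01,
        family_size: int | None = None,
        collapse_technical: bool = False,
    ) -> ComparisonResults:
        """Compare two conditions.

        ``collapse_technical=True`` averages technical replicates to
        biological-replicate profiles before testing; the default uses
        every sample profile as a replicate.
        """
        mats = {}
        for cond in (group_a, group_b):
            sub = self.design[self.design["condition"] == cond]
            if sub.empty:
                raise ValueError(f"condition {cond!r} not present in design")
            if collapse_technical:
                profs = []
                for _, grp in sub.groupby("bio_rep"):
                    m, _, _ = sample_transcriptograms(
                        self.expression[list(grp["sample"])],
                        self.ordering,
                        self.radius,
                    )
                    profs.append(np.nanmean(m, axis=0))
                mats[cond] = np.vstack(profs)
            else:
                m, _, _ = sample_transcriptograms(
                    self.expression[list(sub["sample"])], self.ordering, self.radius
                )
                mats[cond] = m
        return welch_compare(
            mats[group_a],
            mats[group_b],
            family_alpha=family_alpha,
            family_size=family_size,
            group_a=group_a,
            group_b=group_b,
            radius=self.radius,
        )
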