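"""Molecular phenotyping of reporter-gene count matrices.

A targeted RNA count matrix (reporter genes x samples) is turned into
pathway-level phenotypes:

* library-size normalization to log2 counts-per-million,
* single-sample pathway activity scores (mean-rank z score: how far a
  pathway's reporters sit above or below the middle of the per-sample
  expression ranking, standardized by the closed-form null variance of a
  mean of ranks drawn without replacement),
* row z-scoring and peak-time ordering of pathway score profiles,
* subset variance statistics (how much of the total expression variance a
  gene subset carries),
* a one-sided Fisher test for pathway regulation given a set of
  differentially expressed reporters, and
* an ordinary-least-squares polynomial trend test over time or dose.

The activity score is rank-based and therefore invariant under any strictly
monotone per-sample transform of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .knowledge import PathwayGeneAssociations
from .validation import BaselineDistribution, bh_adjust, random_set_baseline

logger = logging.getLogger(__name__)


def log2_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: ``log2((c + pseudocount) / (libsize + 1) * 1e6)``.

    ``counts`` is genes x samples with non-negative integer entries; the
    pseudocount keeps zero counts finite and the library-size offset keeps the
    transform stable for small libraries.
    """
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    lib = values.sum(axis=0)
    if np.any(lib == 0):
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"zero library size in samples: {bad}")
    cpm = (values + pseudocount) / (lib + 1.0) * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.index, columns=counts.columns)


@dataclass(frozen=True)
class ActivityScores:
    """Pathway x sample activity score matrix."""

    frame: pd.DataFrame  # pathways x samples
    method: str
    set_sizes: pd.Series  # scored genes per pathway

    def average_by(self, groups: Mapping[str, str] | pd.Series) -> "ActivityScores":
        """Average scores over replicate samples within each condition.

        ``groups`` maps sample id -> condition label; output columns follow
        the order of first appearance in the input columns.
        """
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        labels = groups.reindex(self.frame.columns)
        if labels.isna().any():
            missing = self.frame.columns[labels.isna()].tolist()
            raise KeyError(f"samples without condition label: {missing}")
        seen: list[str] = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        averaged = pd.DataFrame(
            {lab: self.frame.loc[:, labels[labels == lab].index].mean(axis=1) for lab in seen}
        )
        return ActivityScores(frame=averaged, method=self.method, set_sizes=self.set_sizes)


def _gene_sets_as_dict(
    gene_sets: PathwayGeneAssociations | Mapping[str, frozenset[str] | set[str]],
) -> dict[str, frozenset[str]]:
    if isinstance(gene_sets, PathwayGeneAssociations):
        return gene_sets.membership()
    return {p: frozenset(g) for p, g in gene_sets.items()}


def activity_scores(
    expr: pd.DataFrame,
    gene_sets: PathwayGeneAssociations | Mapping[str, frozenset[str] | set[str]],
    method: str = "meanrank-z",
) -> ActivityScores:
    """Single-sample pathway activity by the mean-rank z score.

    Per sample, all G profiled genes are ranked by expression (ties get the
    average rank).  For a pathway whose m reporters have mean rank R-bar, the
    score is::

        z = (R_bar - (G + 1) / 2) / sqrt((G + 1) * (G - m) / (12 * m))

    i.e. the mean rank standardized by its exact null variance when m ranks
    are drawn without replacement from 1..G, so under exchangeable expression
    the scores have mean 0 and variance ~1.  Positive scores mean the
    pathway's reporters are expressed above the panel average.

    Pathways with no reporter in ``expr`` are skipped with a warning; a
    pathway covering every profiled gene has no contrast (null variance 0)
    and raises ``ValueError``.
    """
    if method != "meanrank-z":
        raise ValueError(f"unknown method {method!r}")
    G = len(expr.index)
    if G < 2:
        raise ValueError("need at least 2 profiled genes")
    sets = _gene_sets_as_dict(gene_sets)
    ranks = expr.rank(axis=0, method="average")  # 1..G per sample
    rows = {}
    sizes = {}
    for pathway, genes in sorted(sets.items()):
        members = sorted(set(genes) & set(expr.index))
        m = len(members)
        if m == 0:
            logger.warning("pathway %r has no profiled reporter; skipped", pathway)
            continue
        if m == G:
            raise ValueError(
                f"pathway {pathway!r} covers all {G} profiled genes; score undefined"
            )
        mean_rank = ranks.loc[members].mean(axis=0)
        null_sd = np.sqrt((G + 1) * (G - m) / (12.0 * m))
        rows[pathway] = (mean_rank - (G + 1) / 2.0) / null_sd
        sizes[pathway] = m
    frame = pd.DataFrame(rows).T
    frame.columns = expr.columns
    return ActivityScores(
        frame=frame, method="meanrank-z", set_sizes=pd.Series(sizes, dtype=int)
    )


def row_zscore(scores: ActivityScores) -> ActivityScores:
    """Z-score each pathway row to zero mean and unit (sample) variance.

    Constant rows become all zeros with a warning.
    """
    frame = scores.frame
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 columns to z-score rows")
    mean = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant activity rows set to zero: %s", frame.index[constant].tolist()
        )
    sd_safe = sd.mask(constant, 1.0)
    z = frame.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[constant] = 0.0
    return ActivityScores(frame=z, method=scores.method + "+rowz", set_sizes=scores.set_sizes)


@dataclass(frozen=True)
class PeakOrdering:
    """Pathways ordered by the time point of maximal activity."""

    order: tuple[str, ...]
    peak_index: pd.Series  # pathway -> argmax column index
    groups: pd.Series  # pathway -> 'early' | 'transient' | 'late'


def peak_time_ordering(scores: ActivityScores, time_order: Sequence[str]) -> PeakOrdering:
    """Sort pathways by the (time-ordered) column where their score peaks.

    The earliest peak time comes first; peak-time ties are broken by pathway
    id.  Pathways peaking at the first time point are labeled ``early``
    (stem-cell-like analog), at the last ``late`` (cell-type-specific
    analog), and in between ``transient`` ('switch' pathways).
    """
    time_order = list(time_order)
    missing = set(time_order) - set(scores.frame.columns)
    if missing:
        raise KeyError(f"time points absent from scores: {sorted(missing)}")
    sub = scores.frame[time_order]
    peak = sub.to_numpy().argmax(axis=1)
    peak_s = pd.Series(peak, index=sub.index)
    order = sorted(sub.index, key=lambda p: (peak_s[p], p))
    last = len(time_order) - 1
    labels = peak_s.map(lambda i: "early" if i == 0 else ("late" if i == last else "transient"))
    return PeakOrdering(order=tuple(order), peak_index=peak_s, groups=labels)


def variance_explained_fraction(
    expr: pd.DataFrame,
    subset: Sequence[str],
    method: str = "varsum",
    n_random: int = 0,
    seed: int = 0,
) -> tuple[float, BaselineDistribution | None]:
    """Fraction of total expression variance attributable to a gene subset.

    ``varsum``: sum of per-gene variances over the subset divided by the sum
    over all genes.  ``projection``: R^2 of regressing every gene's
    (centered) expression profile on the subset's top principal components
    (min(m, samples-1) components).  With ``n_random > 0`` a random-set
    baseline of the same statistic is returned alongside.
    """
    subset_genes = sorted(set(subset) & set(expr.index))
    if not subset_genes:
        raise ValueError("subset shares no genes with the expression matrix")

    def _fraction(genes: Sequence[str]) -> float:
        genes = sorted(set(genes) & set(expr.index))
        if method == "varsum":
            v = expr.var(axis=1, ddof=1)
            total = float(v.sum())
            return float(v.loc[genes].sum() / total) if total > 0 else 0.0
        if method == "projection":
            Yc = expr.to_numpy() - expr.to_numpy().mean(axis=1, keepdims=True)  # genes x n
            total = float((Yc**2).sum())
            if total == 0:
                return 0.0
            X = expr.loc[genes].to_numpy()
            Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x m
            k = min(Xc.shape[1], Xc.shape[0] - 1)
            if k < 1:
                return 0.0
            U, s, _ = np.linalg.svd(Xc, full_matrices=False)
            Uk = U[:, :k][:, s[:k] > 1e-12]
            proj = Yc @ Uk  # genes x k
            return float((proj**2).sum() / total)
        raise ValueError(f"unknown method {method!r}")

    frac = _fraction(subset_genes)
    baseline = None
    if n_random > 0:
        baseline = random_set_baseline(
            universe=list(expr.index),
            size=len(subset_genes),
            n_sets=n_random,
            statistic=lambda g: _fraction(sorted(g)),
            seed=seed,
        )
    return frac, baseline


def pathway_regulation_test(
    de_genes: Sequence[str],
    panel_genes: Sequence[str],
    gene_sets: PathwayGeneAssociations | Mapping[str, frozenset[str] | set[str]],
) -> pd.DataFrame:
    """One-sided Fisher test of whether a pathway's reporters are
    overrepresented among the differentially expressed panel genes.

    The universe is the panel; per pathway the 2x2 table is (DE vs not DE) x
    (reporter of the pathway vs other panel gene).  Returns per-pathway
    ``n_reporters, n_de, overlap, p, q`` with BH adjustment across pathways.
    """
    panel_set = frozenset(panel_genes)
    if not panel_set:
        raise ValueError("panel is empty")
    de_set = frozenset(de_genes)
    if not de_set <= panel_set:
        raise ValueError("de_genes must be a subset of the panel genes")
    sets = _gene_sets_as_dict(gene_sets)
    n = len(panel_set)
    k = len(de_set)
    rows = []
    for pathway, genes in sorted(sets.items()):
        reporters = frozenset(genes) & panel_set
        m = len(reporters)
        x = len(reporters & de_set)
        p = float(stats.hypergeom.sf(x - 1, n, m, k))
        rows.append(
            {"pathway": pathway, "n_reporters": m, "n_de": k, "overlap": x, "p": min(p, 1.0)}
        )
    frame = pd.DataFrame(rows, columns=["pathway", "n_reporters", "n_de", "overlap", "p"])
    frame["q"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else []
    return frame


@dataclass(frozen=True)
class TrendResult:
    """Per-gene polynomial trend test over a time or dose covariate."""

    frame: pd.DataFrame  # gene, linear, quadratic, p, q, direction
    degree: int
    covariate: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[str]:
        return self.frame.loc[self.frame["q"] < alpha, "gene"].tolist()


def _orthonormal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis (without the intercept column), with the
    linear column oriented to correlate positively with x."""
    V = np.vander(x, degree + 1, increasing=True).astype(float)
    Q, _ = np.linalg.qr(V)
    Q = Q[:, 1 : degree + 1]
    for j in range(Q.shape[1]):
        # fix QR sign ambiguity: align column j with x**(j+1)'s centered direction
        if Q[:, j] @ (x ** (j + 1)) < 0:
            Q[:, j] = -Q[:, j]
    return Q


def trend_test(expr: pd.DataFrame, covariate: Sequence[float], degree: int = 2) -> TrendResult:
    """OLS polynomial trend per gene: joint F-test of the polynomial terms
    (degree 2) or a two-sided t-test on the slope (degree 1).

    The covariate is expanded on an orthonormal polynomial basis, so the
    reported linear/quadratic coefficients are contrasts whose signs match
    the raw slope and curvature.  Genes with zero expression variance get
    coefficient 0 and p = 1 by convention.  BH adjustment is applied across
    genes; ``direction`` is the sign of the linear coefficient.
    """
    x = np.asarray(covariate, dtype=float)
    n = x.size
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if expr.shape[1] != n:
        raise ValueError("covariate length must match the number of samples")
    if np.allclose(x, x[0]):
        raise ValueError("covariate is constant")
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} samples for degree {degree}")

    Q = _orthonormal_poly(x, degree)  # n x degree
    Y = expr.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    coefs = Yc @ Q  # genes x degree; orthonormal basis => OLS coefficients
    rss0 = (Yc**2).sum(axis=1)
    explained = (coefs**2).sum(axis=1)
    rss1 = np.maximum(rss0 - explained, 0.0)
    df_resid = n - 1 - degree
    constant = rss0 <= 1e-300

    with np.errstate(divide="ignore", invalid="ignore"):
        if degree == 1:
            se = np.sqrt(rss1 / df_resid)
            t = np.where(se > 0, coefs[:, 0] / se, np.inf * np.sign(coefs[:, 0]))
            p = 2.0 * stats.t.sf(np.abs(t), df_resid)
        else:
            f = (explained / degree) / (rss1 / df_resid)
            p = stats.f.sf(f, degree, df_resid)
    p = np.where(constant, 1.0, p)
    p = np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))
    # a perfect polynomial fit (rss1 == 0) on a non-constant gene: p -> 0
    exact = (~constant) & (rss1 <= 1e-300) & (explained > 0)
    p = np.where(exact, np.nextafter(0.0, 1.0), p)
    coefs = np.where(constant[:, None], 0.0, coefs)

    frame = pd.DataFrame(
        {
            "gene": expr.index,
            "linear": coefs[:, 0],
            "quadratic": coefs[:, 1] if degree == 2 else np.nan,
            "p": p,
            "q": bh_adjust(p),
            "direction": np.sign(coefs[:, 0]).astype(int),
        }
    )
    return TrendResult(frame=frame, degree=degree, covariate=x)


def call_de_genes(
    expr: pd.DataFrame,
    covariate: Sequence[float],
    degree: int = 2,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Call differentially expressed genes from the trend test.

    The log fold-change is the mean expression at the highest covariate level
    minus the mean at the lowest; a gene is DE when |lfc| >= threshold and
    BH-adjusted trend p < alpha.
    """
    x = np.asarray(covariate, dtype=float)
    result = trend_test(expr, x, degree=degree)
    top = expr.loc[:, x == x.max()].mean(axis=1)
    bottom = expr.loc[:, x == x.min()].mean(axis=1)
    lfc = (top - bottom).to_numpy()
    frame = result.frame.copy()
    frame["lfc"] = lfc
    frame["de"] = (np.abs(lfc) >= lfc_threshold) & (frame["q"] < alpha)
    return frame.loc[frame["de"], "gene"].tolist(), frame
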