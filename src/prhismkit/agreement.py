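"""Chance-corrected agreement statistics for ordinal ratings.

Implements weighted/unweighted Cohen's kappa with the Fleiss–Cohen–Everitt
large-sample standard error, normal-approximation confidence intervals,
multi-rater agreement as the mean over all rater pairs with a
delete-one-subject jackknife CI, the kappa z-test used in power analyses,
the two-way random-effects intraclass correlation (absolute agreement,
single rater), and the Landis–Koch interpretation bands.

Notation: for a K x K contingency table with cell proportions p_ij, row
marginals p_i. and column marginals p_.j, and weights w_ij in [0, 1] with
w_ii = 1,

    p_o = sum_ij w_ij p_ij          (weighted observed agreement)
    p_e = sum_ij w_ij p_i. p_.j     (weighted chance agreement)
    kappa_w = (p_o - p_e) / (1 - p_e)

Identity weights (w_ij = 1 iff i = j) recover the unweighted kappa; linear
and quadratic weights give partial credit for near-misses and are the
conventional choices for ordered Likert categories.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WeightScheme",
    "ContingencyTable",
    "KappaEstimate",
    "PairwiseAgreement",
    "IccEstimate",
    "ZTestResult",
    "DegenerateTableError",
    "build_table",
    "weight_matrix",
    "weighted_kappa",
    "kappa_se",
    "bootstrap_kappa_se",
    "kappa_ci",
    "pairwise_mean_kappa",
    "kappa_z_test",
    "icc",
    "interpret_kappa",
    "is_sufficient_agreement",
    "cross_instrument_kappa",
]

SUFFICIENT_KAPPA = 0.61  # conventional "sufficient agreement" threshold


class DegenerateTableError(ValueError):
    """Raised when kappa is undefined (chance agreement p_e = 1)."""


class WeightScheme(str, Enum):
    """Agreement weight for category pair (i, j) on K ordered categories.

    identity : 1 if i == j else 0 (unweighted kappa)
    linear   : 1 - |i - j| / (K - 1)
    quadratic: 1 - (i - j)^2 / (K - 1)^2
    """

    IDENTITY = "identity"
    LINEAR = "linear"
    QUADRATIC = "quadratic"


def weight_matrix(k: int, scheme: WeightScheme | str) -> np.ndarray:
    """K x K agreement weight matrix for the given scheme."""
    if k < 2:
        raise ValueError("need at least 2 categories")
    scheme = WeightScheme(scheme)
    idx = np.arange(k)
    diff = np.abs(idx[:, None] - idx[None, :])
    if scheme is WeightScheme.IDENTITY:
        return (diff == 0).astype(float)
    if scheme is WeightScheme.LINEAR:
        return 1.0 - diff / (k - 1)
    return 1.0 - (diff.astype(float) ** 2) / (k - 1) ** 2


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-classification of two raters over K shared ordered categories."""

    categories: tuple
    counts: np.ndarray
    n: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        k = len(self.categories)
        if k < 2:
            raise ValueError("need at least 2 categories")
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not math.isclose(counts.sum(), self.n):
            raise ValueError("n must equal the sum of counts")
        object.__setattr__(self, "counts", counts)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.categories, self.counts.T, self.n)


@dataclass(frozen=True)
class KappaEstimate:
    kappa: float
    p_o: float
    p_e: float
    se: float
    ci_level: float
    ci_low: float
    ci_high: float
    n: int
    scheme: WeightScheme


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p_value: float
    reject: bool


@dataclass(frozen=True)
class PairwiseAgreement:
    """Mean weighted kappa over all unordered rater pairs with a CI."""

    pair_estimates: tuple
    pair_labels: tuple
    mean_kappa: float
    se: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_subjects: int
    n_pairs: int
    excluded_pairs: tuple = ()
    ci_method: str = "jackknife"


@dataclass(frozen=True)
class IccEstimate:
    icc: float
    model_label: str
    ci_low: float
    ci_high: float
    ci_level: float
    n_subjects: int
    n_raters: int


def _is_na(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip().upper() == "NA":
        return True
    return False


def build_table(x: Sequence, y: Sequence,
                categories: Sequence) -> ContingencyTable:
    """Cross-tabulate two equal-length rating vectors.

    Subjects where either rating is NA (None, NaN or the token "NA") are
    dropped pairwise.  Every retained value must belong to ``categories``,
    whose order defines the ordinal structure of both table axes.
    """
    if len(x) != len(y):
        raise ValueError("rating vectors must have equal length")
    categories = tuple(categories)
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    counts = np.zeros((k, k))
    retained = 0
    for xv, yv in zip(x, y):
        if _is_na(xv) or _is_na(yv):
            continue
        try:
            i, j = index[xv], index[yv]
        except (KeyError, TypeError):
            bad = xv if xv not in index else yv
            raise ValueError(f"value {bad!r} not in declared categories {categories}")
        counts[i, j] += 1
        retained += 1
    if retained == 0:
        raise ValueError("no subjects retained after pairwise NA removal")
    return ContingencyTable(categories, counts, retained)


def _po_pe(table: ContingencyTable, w: np.ndarray):
    p = table.counts / table.n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float(r @ w @ c)
    return p, r, c, p_o, p_e


def weighted_kappa(table: ContingencyTable,
                   scheme: WeightScheme | str = WeightScheme.QUADRATIC,
                   level: float = 0.95) -> KappaEstimate:
    """Weighted Cohen's kappa with large-sample SE and normal CI.

    Raises :class:`DegenerateTableError` when both marginals put all mass
    on the same single category (p_e = 1, kappa undefined).
    """
    scheme = WeightScheme(scheme)
    w = weight_matrix(len(table.categories), scheme)
    _, _, _, p_o, p_e = _po_pe(table, w)
    if p_e >= 1.0 - 1e-12:
        raise DegenerateTableError(
            f"chance agreement p_e = {p_e:.6f}: both raters concentrate all "
            "mass on one identical category, kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = kappa_se(table, scheme)
    lo, hi = kappa_ci(kappa, se, level)
    return KappaEstimate(kappa=kappa, p_o=p_o, p_e=p_e, se=se, ci_level=level,
                         ci_low=lo, ci_high=hi, n=table.n, scheme=scheme)


def kappa_se(table: ContingencyTable,
             scheme: WeightScheme | str = WeightScheme.QUADRATIC) -> float:
    """Large-sample (Fleiss–Cohen–Everitt) standard error of weighted kappa.

    Non-null form: with wbar_i. = sum_j w_ij p_.j and wbar_.j = sum_i
    w_ij p_i.,

      var = [ sum_ij p_ij (w_ij (1-p_e) - (wbar_i. + wbar_.j)(1-p_o))^2
              - (p_o p_e - 2 p_e + p_o)^2 ] / (n (1-p_e)^4)

    Zero for a perfect-agreement table; scales as 1/sqrt(n).
    """
    scheme = WeightScheme(scheme)
    w = weight_matrix(len(table.categories), scheme)
    p, r, c, p_o, p_e = _po_pe(table, w)
    if p_e >= 1.0 - 1e-12:
        raise DegenerateTableError("p_e = 1: SE of kappa undefined")
    wbar_row = w @ c          # wbar_i. over columns' marginal
    wbar_col = w.T @ r        # wbar_.j over rows' marginal
    term = (w * (1 - p_e) - (wbar_row[:, None] + wbar_col[None, :]) * (1 - p_o)) ** 2
    var = ((p * term).sum() - (p_o * p_e - 2 * p_e + p_o) ** 2)
    var /= table.n * (1 - p_e) ** 4
    return float(np.sqrt(max(var, 0.0)))


def bootstrap_kappa_se(table: ContingencyTable,
                       scheme: WeightScheme | str = WeightScheme.QUADRATIC,
                       n_boot: int = 2000,
                       seed: Optional[int] = None) -> float:
    """Nonparametric bootstrap SE of weighted kappa (cross-check for
    :func:`kappa_se`): resamples subjects from the table's empirical
    distribution; degenerate resamples are skipped."""
    rng = np.random.default_rng(seed)
    k = len(table.categories)
    w = weight_matrix(k, WeightScheme(scheme))
    probs = (table.counts / table.n).ravel()
    kappas = []
    for _ in range(n_boot):
        counts = rng.multinomial(table.n, probs).reshape(k, k).astype(float)
        p = counts / table.n
        r, c = p.sum(axis=1), p.sum(axis=0)
        p_o = (w * p).sum()
        p_e = r @ w @ c
        if p_e >= 1.0 - 1e-12:
            continue
        kappas.append((p_o - p_e) / (1 - p_e))
    if len(kappas) < 2:
        raise DegenerateTableError("bootstrap produced no valid resamples")
    return float(np.std(kappas, ddof=1))


def kappa_ci(kappa: float, se: float, level: float) -> tuple:
    """Normal-approximation CI ``kappa +/- z_{(1+level)/2} * se``.

    Not truncated to [-1, 1]; a warning is issued if a limit falls
    outside that range.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = kappa - z * se, kappa + z * se
    if lo < -1.0 or hi > 1.0:
        warnings.warn(
            f"normal-approximation CI ({lo:.3f}, {hi:.3f}) extends outside "
            "[-1, 1]; reported as computed", stacklevel=2)
    return float(lo), float(hi)


def _pair_kappa_mean(matrix: np.ndarray, categories: tuple, w: np.ndarray,
                     pairs: list) -> tuple:
    """Mean kappa over rater pairs for one subject subset.

    Returns (mean, n_valid_pairs); degenerate pairs are skipped.
    """
    vals = []
    for a, b in pairs:
        tab = _table_from_columns(matrix[:, a], matrix[:, b], categories)
        if tab is None:
            continue
        counts, n = tab
        p = counts / n
        r, c = p.sum(axis=1), p.sum(axis=0)
        p_o = (w * p).sum()
        p_e = r @ w @ c
        if p_e >= 1.0 - 1e-12:
            continue
        vals.append((p_o - p_e) / (1 - p_e))
    if not vals:
        return np.nan, 0
    return float(np.mean(vals)), len(vals)


def _table_from_columns(x: np.ndarray, y: np.ndarray, categories: tuple):
    """Counts and n for one rater pair, or None if nothing retained."""
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    counts = np.zeros((k, k))
    n = 0
    for xv, yv in zip(x, y):
        if _is_na(xv) or _is_na(yv):
            continue
        counts[index[xv], index[yv]] += 1
        n += 1
    if n == 0:
        return None
    return counts, n


def _jackknife_se(matrix: np.ndarray, categories: tuple, w: np.ndarray,
                  kept_pairs: list) -> float:
    """Delete-one-subject jackknife SE of the mean-of-pairs kappa.

    Dispatches to the vectorised engine when the matrix is complete (no
    NAs) and every rater pair is usable; otherwise falls back to explicit
    leave-one-out recomputation with pairwise NA handling.
    """
    n_sub, n_rat = matrix.shape
    all_pairs = list(itertools.combinations(range(n_rat), 2))
    complete = not any(_is_na(v) for v in matrix.ravel())
    if complete and kept_pairs == all_pairs:
        from ._fastkappa import mean_kappa_jackknife_batch
        index = {c: i for i, c in enumerate(categories)}
        codes = np.vectorize(index.__getitem__)(matrix).astype(np.int64)
        _, se, degen = mean_kappa_jackknife_batch(codes[None], w)
        if not degen[0]:
            return float(se[0])
    loo = []
    for i in range(n_sub):
        sub = np.delete(matrix, i, axis=0)
        m, nv = _pair_kappa_mean(sub, categories, w, kept_pairs)
        if nv > 0:
            loo.append(m)
    loo = np.asarray(loo)
    m = len(loo)
    if m < 2:
        return 0.0
    return float(np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum()))


def pairwise_mean_kappa(ratings, scheme: WeightScheme | str = WeightScheme.QUADRATIC,
                        level: float = 0.90,
                        categories: Optional[Sequence] = None,
                        ci_method: str = "jackknife",
                        rater_labels: Optional[Sequence[str]] = None
                        ) -> PairwiseAgreement:
    """Multi-rater agreement as the average weighted kappa over all
    C(R, 2) rater pairs, with a CI for the mean.

    ``ratings`` is a subjects x raters array of ordinal values (NA allowed;
    dropped pairwise within each pair).  With 6 raters this averages the
    15 distinct pair kappas.

    The default CI is a delete-one-subject jackknife of the mean-of-pairs,
    which accounts for the dependence induced by shared subjects.
    ``ci_method="independent"`` instead treats the pair kappas as
    independent and uses a naive normal CI of their mean — provided for
    comparison only, since it understates the variance.

    Pairs whose table is degenerate (p_e = 1) are excluded from the mean
    with a warning.
    """
    matrix = np.asarray(ratings, dtype=object)
    if matrix.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters array")
    n_sub, n_rat = matrix.shape
    if n_rat < 2 or n_sub < 2:
        raise ValueError("need at least 2 raters and 2 subjects")
    if categories is None:
        observed = {v for v in matrix.ravel() if not _is_na(v)}
        categories = tuple(sorted(observed))
    else:
        categories = tuple(categories)
    if len(categories) < 2:
        raise ValueError("fewer than 2 distinct categories observed; "
                         "pass an explicit category list")
    scheme = WeightScheme(scheme)
    w = weight_matrix(len(categories), scheme)
    if rater_labels is None:
        rater_labels = [f"r{i+1}" for i in range(n_rat)]

    pairs = list(itertools.combinations(range(n_rat), 2))
    estimates, labels, excluded, kept_pairs = [], [], [], []
    for a, b in pairs:
        lab = f"{rater_labels[a]}-{rater_labels[b]}"
        try:
            tab = build_table(matrix[:, a], matrix[:, b], categories)
            est = weighted_kappa(tab, scheme, level=level)
        except (DegenerateTableError, ValueError) as exc:
            warnings.warn(f"rater pair {lab} excluded from the mean: {exc}",
                          stacklevel=2)
            excluded.append(lab)
            continue
        estimates.append(est)
        labels.append(lab)
        kept_pairs.append((a, b))
    if not estimates:
        raise DegenerateTableError("every rater pair is degenerate")

    mean_k = float(np.mean([e.kappa for e in estimates]))

    if ci_method == "independent":
        # naive: pair kappas treated as independent
        se = float(np.sqrt(sum(e.se ** 2 for e in estimates)) / len(estimates))
    elif ci_method == "jackknife":
        se = _jackknife_se(matrix, categories, w, kept_pairs)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    lo, hi = kappa_ci(mean_k, se, level)
    return PairwiseAgreement(
        pair_estimates=tuple(estimates), pair_labels=tuple(labels),
        mean_kappa=mean_k, se=se, ci_low=lo, ci_high=hi, ci_level=level,
        n_subjects=n_sub, n_pairs=len(estimates), excluded_pairs=tuple(excluded),
        ci_method=ci_method,
    )


def kappa_z_test(kappa_hat: float, kappa0: float, se: float,
                 alpha: float = 0.10) -> ZTestResult:
    """Two-sided normal z-test of H0: kappa = kappa0.

    ``z = (kappa_hat - kappa0) / se``; ``p = 2 (1 - Phi(|z|))``; rejects
    when p < alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if se <= 0:
        if se == 0 and kappa_hat == kappa0:
            return ZTestResult(z=0.0, p_value=1.0, reject=False)
        raise ValueError("se must be positive")
    z = (kappa_hat - kappa0) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(z=float(z), p_value=float(p), reject=bool(p < alpha))


def icc(scores, level: float = 0.95) -> IccEstimate:
    """Two-way random-effects, absolute-agreement, single-rater ICC.

    ``scores`` is a subjects x raters matrix of continuous values; rows
    containing missing values are deleted listwise.  The point estimate
    comes from the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the standard F-based confidence interval (McGraw & Wong's
    ICC(A,1)).  When the between-subject variance is zero the estimate is
    reported at the 0 boundary with a warning.
    """
    m = np.asarray(scores, dtype=float)
    if m.ndim != 2:
        raise ValueError("scores must be a 2-D subjects x raters matrix")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters after "
                         "listwise deletion")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    # relative tolerance: ss_rows == 0 leaves msr at rounding-error scale
    at_boundary = msr <= mse + 1e-10 * (abs(msr) + abs(msc) + abs(mse))
    if denom <= 0 or at_boundary:
        warnings.warn("between-subject variance does not exceed error "
                      "variance; ICC reported at the 0 boundary",
                      stacklevel=2)
    value = 0.0 if (denom <= 0 or at_boundary) else float((msr - mse) / denom)

    # F-based CI for ICC(A,1)
    alpha = 1.0 - level
    r = max(value, 0.0)
    if mse <= 0:  # perfect agreement, zero error variance
        lo = hi = value
    else:
        a = k * r / (n * (1 - r)) if r < 1 else np.inf
        b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            lo = hi = value
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lo = min(float(lo), value)
    hi = max(float(hi), value)
    return IccEstimate(icc=value, model_label="two-way random, absolute "
                       "agreement, single rater (ICC(A,1))",
                       ci_low=lo, ci_high=hi, ci_level=level,
                       n_subjects=n, n_raters=k)


_LANDIS_KOCH = [
    (0.00, "no agreement"),
    (0.21, "slight"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "substantial"),
    (1.01, "almost perfect"),
]


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch verbal interpretation of a kappa value.

    <0 no agreement; 0.00–0.20 slight; 0.21–0.40 fair; 0.41–0.60 moderate;
    0.61–0.80 substantial; 0.81–1.00 almost perfect.
    """
    if kappa > 1.0 + 1e-9:
        raise ValueError("kappa cannot exceed 1")
    for upper, label in _LANDIS_KOCH:
        if kappa < upper - 1e-12:
            return label
    return "almost perfect"


def is_sufficient_agreement(kappa: float) -> bool:
    """Whether agreement reaches the conventional 0.61 'sufficient' mark."""
    return kappa >= SUFFICIENT_KAPPA


def cross_instrument_kappa(a: Sequence, b: Sequence,
                           scale_a: Sequence, scale_b: Sequence,
                           scheme: WeightScheme | str = WeightScheme.QUADRATIC,
                           level: float = 0.95) -> KappaEstimate:
    """Weighted kappa between ratings given on two different ordinal scales.

    Both scales must be declared as ordered lists of consecutive integers
    (e.g. 0–4 and 1–5).  Each is shifted to a common 0-based support
    (value minus the scale minimum); the kappa is then computed on the
    union of the shifted supports.  Distances between categories are never
    rescaled — a one-step disagreement on either instrument counts the
    same.
    """
    scale_a, scale_b = list(scale_a), list(scale_b)
    for s in (scale_a, scale_b):
        if sorted(s) != list(range(min(s), min(s) + len(s))):
            raise ValueError(f"scale {s} is not a run of consecutive integers; "
                             "cannot align onto a common ordinal support")
    shift_a, shift_b = min(scale_a), min(scale_b)
    k = max(len(scale_a), len(scale_b))
    categories = tuple(range(k))
    xa = [v if _is_na(v) else int(v) - shift_a for v in a]
    xb = [v if _is_na(v) else int(v) - shift_b for v in b]
    table = build_table(xa, xb, categories)
    return weighted_kappa(table, scheme, level=level)
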