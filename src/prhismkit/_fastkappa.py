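"""Vectorised batched engines for mean pairwise weighted kappa.

These operate on dense integer rating matrices with no missing values and
are shared by the power simulation (thousands of replicates per call) and
by the public agreement API, which dispatches here for the delete-one-
subject jackknife whenever the input has no NAs.  All functions take
``x`` of shape (B, n, R) with values in [0, K) and a K x K weight matrix.
"""

from __future__ import annotations

import itertools

import numpy as np

_EPS = 1e-9


def pair_counts_batch(x: np.ndarray, k: int):
    """(B, P, K, K) contingency counts for every rater pair of every
    replicate, plus the per-pair rating columns (B, n, P) of each rater."""
    b, n, r = x.shape
    ia, ib = map(np.array, zip(*itertools.combinations(range(r), 2)))
    p = len(ia)
    xa = x[:, :, ia]
    xb = x[:, :, ib]
    cell = xa * k + xb
    offs = (np.arange(b)[:, None, None] * p + np.arange(p)[None, None, :]) * k * k
    flat = np.bincount((offs + cell).ravel(), minlength=b * p * k * k)
    return flat.reshape(b, p, k, k).astype(float), xa, xb


def mean_kappa_jackknife_batch(x: np.ndarray, w: np.ndarray):
    """Mean pairwise kappa and delete-one-subject jackknife SE.

    Returns (mean_kappa (B,), jackknife_se (B,), degenerate (B,)) where
    ``degenerate`` marks replicates in which any rater pair — at full
    sample or in any leave-one-out subsample — has chance agreement 1.
    On clean input this reproduces exactly the one-pair-at-a-time
    computation of :func:`prhismkit.agreement.pairwise_mean_kappa`.
    """
    b, n, r = x.shape
    k = w.shape[0]
    counts, xa, xb = pair_counts_batch(x, k)

    s_o = np.einsum("bpij,ij->bp", counts, w)
    rows = counts.sum(axis=3)             # (B, P, K)
    cols = counts.sum(axis=2)
    s_e = np.einsum("bpi,ij,bpj->bp", rows, w, cols)
    p_o = s_o / n
    p_e = s_e / n ** 2
    degen = p_e >= 1.0 - _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa_pairs = (p_o - p_e) / (1.0 - p_e)
    mean_kappa = kappa_pairs.mean(axis=1)

    # leave-one-subject-out kappas, vectorised over subjects:
    # removing subject i downdates S_o by w[x_i, y_i] and S_e by the two
    # marginal cross-terms, so no table is ever rebuilt.
    xat = xa.transpose(0, 2, 1)           # (B, P, n)
    xbt = xb.transpose(0, 2, 1)
    w_xy = w[xat, xbt]
    u = np.einsum("ij,bpj->bpi", w, cols)    # (w @ c)_a
    v = np.einsum("ij,bpi->bpj", w, rows)    # (w^T @ r)_b
    u_g = np.take_along_axis(u, xat, axis=2)
    v_g = np.take_along_axis(v, xbt, axis=2)
    s_o_i = s_o[:, :, None] - w_xy
    s_e_i = s_e[:, :, None] - u_g - v_g + w_xy
    p_o_i = s_o_i / (n - 1)
    p_e_i = s_e_i / (n - 1) ** 2
    degen |= (p_e_i >= 1.0 - _EPS).any(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa_i = (p_o_i - p_e_i) / (1.0 - p_e_i)
    theta_i = kappa_i.mean(axis=1)        # (B, n) LOO mean-of-pairs
    theta_bar = theta_i.mean(axis=1, keepdims=True)
    var_jack = (n - 1) / n * ((theta_i - theta_bar) ** 2).sum(axis=1)
    se = np.sqrt(np.maximum(var_jack, 0.0))
    return mean_kappa, se, degen.any(axis=1)


def mean_kappa_independent_batch(x: np.ndarray, w: np.ndarray):
    """Mean pairwise kappa with the naive independent-pairs SE.

    Propagates each pair's Fleiss–Cohen–Everitt large-sample SE as if the
    C(R,2) pair kappas were independent: ``se = sqrt(sum se_p^2) / P``.
    Because the pairs share subjects (and each rater appears in R-1
    pairs), this understates the variance of the mean; it exists only to
    mirror analyses that make the independence assumption.
    """
    b, n, r = x.shape
    k = w.shape[0]
    counts, _, _ = pair_counts_batch(x, k)
    p_tab = counts / n
    rows = p_tab.sum(axis=3)
    cols = p_tab.sum(axis=2)
    p_o = np.einsum("bpij,ij->bp", p_tab, w)
    p_e = np.einsum("bpi,ij,bpj->bp", rows, w, cols)
    degen = (p_e >= 1.0 - _EPS).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa_pairs = (p_o - p_e) / (1.0 - p_e)
        wbar_r = np.einsum("ij,bpj->bpi", w, cols)
        wbar_c = np.einsum("ij,bpi->bpj", w, rows)
        term = (w[None, None] * (1 - p_e)[..., None, None]
                - (wbar_r[..., :, None] + wbar_c[..., None, :])
                * (1 - p_o)[..., None, None]) ** 2
        var = (np.einsum("bpij,bpij->bp", p_tab, term)
               - (p_o * p_e - 2 * p_e + p_o) ** 2) / (n * (1 - p_e) ** 4)
    var = np.maximum(var, 0.0)
    n_pairs = kappa_pairs.shape[1]
    mean_kappa = kappa_pairs.mean(axis=1)
    se = np.sqrt(var.sum(axis=1)) / n_pairs
    return mean_kappa, se, degen
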