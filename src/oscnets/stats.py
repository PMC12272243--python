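"""Permutation GLM statistics with maximum-statistic multiple-comparison
control.

A general linear model ``Y = X B + E`` is fitted by ordinary least
squares per element (e.g. per time point and network), and a contrast of
the parameter estimates (COPE) is tested against a permutation null.
Family-wise error across elements is controlled by recording, for each
permutation, the maximum absolute COPE over all elements; an observed
element is significant when its |COPE| exceeds the (1-alpha) quantile of
that null distribution.

For a one-sample test (mean over subjects differs from zero) the
exchangeability operation is a per-subject sign flip of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlmResult",
    "condition_contrast",
    "glm_max_stat_test",
    "one_sample_max_stat_test",
]


@dataclass
class GlmResult:
    """Observed COPEs, per-element p-values and the max-statistic null.

    ``copes`` and ``pvalues`` have the element shape of the input data;
    ``null`` holds one maximum per permutation (the first entry is the
    observed labelling).  ``significant`` is ``pvalues < alpha``.
    """

    copes: np.ndarray
    pvalues: np.ndarray
    null: np.ndarray
    alpha: float

    @property
    def significant(self):
        return self.pvalues < self.alpha

    @property
    def threshold(self):
        """|COPE| threshold at the configured alpha."""
        return float(np.quantile(self.null, 1.0 - self.alpha))


def _as_matrix(data):
    data = np.asarray(data, dtype=float)
    shape = data.shape[1:]
    return data.reshape(data.shape[0], -1), shape


def one_sample_max_stat_test(data, n_perm=1000, alpha=0.05, seed=None):
    """One-sample max-|COPE| sign-flipping permutation test.

    ``data`` is [subjects x ...]; the COPE is the subject mean per
    element.  ``n_perm`` random sign assignments (the first permutation
    is the identity) build the null of the maximum absolute mean; the
    p-value for each element is ``(1 + #{null >= |cope|}) / (1 + n_perm)``
    (two-tailed by symmetry of the sign-flip null).
    """
    Y, shape = _as_matrix(data)
    S, E = Y.shape
    if S < 2:
        raise ValueError("need at least two subjects")
    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    signs[0] = 1.0  # observed labelling first
    perm_copes = (signs @ Y) / S  # [n_perm x E]
    null = np.abs(perm_copes).max(axis=1)
    copes = perm_copes[0]
    pvals = (1.0 + (null[:, None] >= np.abs(copes)[None, :]).sum(axis=0)) / (
        1.0 + n_perm
    )
    return GlmResult(
        copes=copes.reshape(shape),
        pvalues=pvals.reshape(shape),
        null=null,
        alpha=alpha,
    )


def condition_contrast(responses, weights):
    """Per-subject weighted combination of per-condition responses.

    ``responses`` is a sequence with one entry per subject, each a
    mapping from condition name to that subject's trial-averaged
    response array (all conditions sharing one shape).  ``weights`` maps
    condition names to contrast weights, e.g. ``{"famous": 0.5,
    "unfamiliar": 0.5, "scrambled": -1.0}`` for faces minus scrambled.
    Returns an array [subjects x ...] suitable for a one-sample test.
    """
    if not responses:
        raise ValueError("need at least one subject")
    if not weights:
        raise ValueError("need at least one condition weight")
    out = []
    for s, conds in enumerate(responses):
        total = None
        for name, w in weights.items():
            if name not in conds:
                raise ValueError(
                    f"subject {s} is missing condition {name!r}"
                )
            term = w * np.asarray(conds[name], dtype=float)
            total = term if total is None else total + term
        out.append(total)
    return np.stack(out)


def glm_max_stat_test(
    data, design, contrast, n_perm=1000, alpha=0.05, seed=None
):
    """Max-|COPE| permutation test for a general design.

    ``data`` is [observations x ...], ``design`` [observations x
    regressors] and ``contrast`` a length-regressors vector.  The null is
    built by permuting the rows of the design (first permutation =
    identity) and recording the maximum |COPE| over elements.
    """
    Y, shape = _as_matrix(data)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    c = np.asarray(contrast, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and data disagree on observations")
    if c.shape != (X.shape[1],):
        raise ValueError("contrast length must match the regressors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if not np.any(c):
        raise ValueError("contrast must be non-zero")
    n_perm = int(n_perm)
    rng = np.random.default_rng(seed)

    def _cope(Xp):
        beta = np.linalg.lstsq(Xp, Y, rcond=None)[0]
        return c @ beta

    copes = _cope(X)
    null = np.empty(n_perm)
    null[0] = np.abs(copes).max()
    for p in range(1, n_perm):
        null[p] = np.abs(_cope(X[rng.permutation(X.shape[0])])).max()
    pvals = (1.0 + (null[:, None] >= np.abs(copes)[None, :]).sum(axis=0)) / (
        1.0 + n_perm
    )
    return GlmResult(
        copes=copes.reshape(shape),
        pvalues=pvals.reshape(shape),
        null=null,
        alpha=alpha,
    )
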