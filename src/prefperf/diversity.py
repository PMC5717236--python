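"""Shannon entropy and Hill-number (numbers-equivalent) diversity of host use.

Diet breadth is measured as the *effective number of host plants*: the Hill
number of order ``q`` of a species' host-use profile. At ``q = 1`` this is
``exp(H)`` with ``H`` the Shannon entropy of the use proportions — the number
of equally common hosts that would yield the same entropy. A strict monophage
scores 1; a species using ``k`` hosts evenly scores exactly ``k``.

Profiles are raw non-negative weights (egg counts or survival proportions per
host); normalisation to proportions is internal, so results are invariant to
the overall scale of a column.
"""

from __future__ import annotations

import numpy as np

from .data import InteractionMatrix

__all__ = [
    "shannon_entropy",
    "hill_diversity",
    "species_alpha",
    "jost_community_alpha",
]


def _proportions(weights) -> np.ndarray:
    """Validate a weight profile and return its positive-support proportions."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1:
        raise ValueError("profile must be one-dimensional")
    if np.any(np.isnan(w)):
        w = w[~np.isnan(w)]
    if w.size == 0 or np.any(w < 0):
        raise ValueError("profile must be non-negative and non-empty")
    total = w.sum()
    if total <= 0:
        raise ValueError("profile has no positive weight; diversity is undefined")
    # zero weights contribute nothing at q >= 1 and break p**q at q < 1
    p = w[w > 0] / total
    return p


def shannon_entropy(weights) -> float:
    """Shannon entropy H = -sum p_j ln p_j (nats) of a host-use profile.

    Zero weights follow the 0 ln 0 = 0 convention; an all-zero profile raises
    ``ValueError``.
    """
    p = _proportions(weights)
    return float(-(p * np.log(p)).sum())


def hill_diversity(weights, order_q: float = 1.0) -> float:
    """Hill number of order *q*: the effective number of equally common hosts.

    ``D_q = (sum p_j^q)^(1/(1-q))`` for ``q != 1`` and ``exp(H)`` at the
    ``q = 1`` limit. Scale-invariant in the raw weights; always in
    ``[1, support size]``.
    """
    if order_q < 0:
        raise ValueError("order_q must be >= 0")
    p = _proportions(weights)
    if abs(order_q - 1.0) < 1e-9:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**order_q).sum() ** (1.0 / (1.0 - order_q)))


def species_alpha(matrix: InteractionMatrix, order_q: float = 1.0) -> dict[str, float]:
    """Per-species diet breadth: column-wise Hill diversity of an interaction matrix.

    This is the degree-of-specialisation covariate used downstream. A column
    with no positive interaction raises ``ValueError`` naming the species.
    """
    out: dict[str, float] = {}
    for species in matrix.col_labels:
        col = matrix.column(species)
        try:
            out[species] = hill_diversity(col, order_q)
        except ValueError as exc:
            raise ValueError(f"species {species!r}: {exc}") from exc
    return out


def jost_community_alpha(
    matrix: InteractionMatrix, order_q: float = 1.0, column_weights=None
) -> float:
    """Community-level alpha diversity under multiplicative partitioning.

    With column weights ``w_i`` (default equal), the ``q = 1`` alpha is
    ``exp(sum_i w_i H_i)`` — the weighted geometric mean of the per-species
    effective host numbers. For ``q != 1`` the weighted-sum form
    ``[sum_i sum_j (w_i p_ij)^q / sum_i w_i^q]^(1/(1-q))`` is used. When all
    columns share one Hill value the community alpha equals it.
    """
    n_cols = len(matrix.col_labels)
    if column_weights is None:
        w = np.full(n_cols, 1.0 / n_cols)
    else:
        w = np.asarray(column_weights, dtype=float)
        if w.shape != (n_cols,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("column_weights must be non-negative and sum to 1")
    if abs(order_q - 1.0) < 1e-9:
        entropies = [
            shannon_entropy(matrix.column(s)) for s in matrix.col_labels
        ]
        return float(np.exp(np.dot(w, entropies)))
    acc = 0.0
    for i, species in enumerate(matrix.col_labels):
        p = _proportions(matrix.column(species))
        acc += ((w[i] * p) ** order_q).sum()
    return float((acc / (w**order_q).sum()) ** (1.0 / (1.0 - order_q)))
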