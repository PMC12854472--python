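"""Pooled within-group phenotypic covariance (P standing in for G).

Specimens are centered on their taxon x sex cell means (equivalent to the
residuals of a full-factorial MANOVA on those factors), the residual
cross-product is pooled, the result is scaled by heritability, and the
inverse (or pseudo-inverse for ill-conditioned matrices) is exposed with
diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import Phylogeny, TraitTable

__all__ = [
    "PooledW",
    "residualize",
    "pooled_within_cov",
    "apply_heritability",
    "invert_w",
    "pooled_w_for_taxa",
    "descendant_taxa",
]

logger = logging.getLogger(__name__)

SMALL_SAMPLE_N = 40
_RCOND = 1e-10


@dataclass(frozen=True)
class PooledW:
    matrix: np.ndarray
    taxa_used: tuple[str, ...]
    n_specimens: int
    n_groups: int
    h2_applied: bool = False
    condition_number: float = np.nan

    def __post_init__(self):
        W = np.asarray(self.matrix, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-8 * max(1.0, np.abs(W).max())):
            raise ValueError("W must be symmetric")
        object.__setattr__(self, "matrix", W)
        object.__setattr__(
            self, "condition_number", float(np.linalg.cond(W)) if W.size else np.nan
        )

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


def residualize(traits: TraitTable, factors: tuple[str, ...] = ("taxon", "sex")) -> np.ndarray:
    """Center each specimen on its factor-cell mean (full factorial model).

    Identical to the residuals of a least-squares fit on the taxon x sex
    indicator design; residuals sum to zero within every cell.
    """
    df = traits.to_frame()
    z = traits.z
    cells = df.groupby(list(factors), sort=False)
    out = np.empty_like(z)
    for _, idx in cells.indices.items():
        out[idx] = z[idx] - z[idx].mean(axis=0)
    return out


def pooled_within_cov(
    residuals: np.ndarray,
    n_groups: int,
    taxa_used: tuple[str, ...] = (),
    divisor: str = "n_minus_g",
) -> PooledW:
    """Residual cross-product over (n - g) (or n with ``divisor="n"``)."""
    R = np.asarray(residuals, dtype=float)
    n = R.shape[0]
    d = n - n_groups if divisor == "n_minus_g" else n
    if d <= 0:
        raise ValueError(f"non-positive divisor: n={n}, groups={n_groups}")
    W = (R.T @ R) / d
    W = (W + W.T) / 2.0
    if n < SMALL_SAMPLE_N:
        msg = f"pooled sample size n={n} < {SMALL_SAMPLE_N}; P-matrix may be unstable"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return PooledW(matrix=W, taxa_used=tuple(taxa_used), n_specimens=n, n_groups=n_groups)


def apply_heritability(W: PooledW, h2: float) -> PooledW:
    """Scale the phenotypic matrix to an additive-genetic proxy: W' = h2 * W."""
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    if W.h2_applied:
        raise ValueError("heritability already applied")
    return replace(W, matrix=h2 * W.matrix, h2_applied=True)


def invert_w(W: PooledW, rcond: float = _RCOND) -> tuple[np.ndarray, dict]:
    """Exact inverse when well conditioned; Moore-Penrose fallback otherwise.

    Returns (W_inv, diagnostics) where diagnostics records the condition
    number and whether the pseudo-inverse path was taken.
    """
    M = W.matrix
    if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
        raise ValueError("non-symmetric matrix")
    cond = W.condition_number
    pseudo = not np.isfinite(cond) or cond > 1.0 / rcond
    if pseudo:
        msg = f"ill-conditioned W (cond={cond:.3g}); using pseudo-inverse"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        inv = np.linalg.pinv(M, rcond=rcond, hermitian=True)
    else:
        inv = np.linalg.inv(M)
    inv = (inv + inv.T) / 2.0
    return inv, {"condition_number": cond, "pseudo_inverse": pseudo}


def descendant_taxa(tree: Phylogeny, node: int) -> list[str]:
    """Tip labels of the clade rooted at ``node``."""
    kids = tree.children()
    out = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd in tree.tip_label:
            out.append(tree.tip_label[nd])
        else:
            stack.extend(kids.get(nd, []))
    return sorted(out)


def pooled_w_for_taxa(
    traits: TraitTable,
    taxa: list[str],
    h2: float | None = None,
    divisor: str = "n_minus_g",
) -> PooledW:
    """Build the pooled within-group W from the given taxa's specimens."""
    sub = traits.subset_taxa(taxa)
    R = residualize(sub)
    n_groups = len(sub.to_frame().groupby(["taxon", "sex"], sort=False))
    W = pooled_within_cov(R, n_groups, taxa_used=tuple(sorted(taxa)), divisor=divisor)
    if h2 is not None:
        W = apply_heritability(W, h2)
    return W
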