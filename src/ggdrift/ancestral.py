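"""Ancestral trait estimation under single-rate Brownian motion.

Point estimates for internal nodes are the maximum-likelihood values: the
configuration minimizing the branch-length-weighted sum of squared changes
over the tree.  With edge weights 1/v this is a graph-Laplacian linear
system, solved once for all traits.  Confidence intervals come from the
conditional normal variance of internal states given the tips, with the
per-trait BM rate estimated by ML from the tip data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Phylogeny

__all__ = ["AncestralStates", "tip_means", "estimate_ancestral_states"]

logger = logging.getLogger(__name__)

_ZERO_BRANCH_EPS = 1e-8


@dataclass(frozen=True)
class AncestralStates:
    """Per-internal-node, per-trait estimates with 95% CIs.

    ``estimate``/``ci_lower``/``ci_upper`` are DataFrames indexed by
    internal node id (preorder from the root), columns = trait names.
    """

    estimate: pd.DataFrame
    ci_lower: pd.DataFrame
    ci_upper: pd.DataFrame
    sigma2: pd.Series  # ML BM rate per trait

    def __post_init__(self):
        if not (
            (self.ci_lower.to_numpy() <= self.estimate.to_numpy() + 1e-12).all()
            and (self.estimate.to_numpy() <= self.ci_upper.to_numpy() + 1e-12).all()
        ):
            raise ValueError("CI bounds must bracket the estimates")
        if not np.all(np.isfinite(self.estimate.to_numpy())):
            raise ValueError("non-finite ancestral estimates")

    def vector(self, node: int) -> np.ndarray:
        return self.estimate.loc[node].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        """Write rows = internal nodes, columns = (estimate, lo, hi) per trait."""
        blocks = []
        for trait in self.estimate.columns:
            blocks.append(
                pd.DataFrame(
                    {
                        f"{trait}": self.estimate[trait],
                        f"{trait}_lo": self.ci_lower[trait],
                        f"{trait}_hi": self.ci_upper[trait],
                    }
                )
            )
        out = pd.concat(blocks, axis=1)
        out.index.name = "node"
        out.to_csv(path, sep="\t")


def tip_means(traits) -> pd.DataFrame:
    """Arithmetic mean of (logged) trait values per taxon.

    Returns a DataFrame indexed by taxon, columns = trait names.
    """
    df = traits.to_frame()
    means = df.groupby("taxon", sort=True)[list(traits.trait_names)].mean()
    if means.isna().any().any():
        raise ValueError("empty taxon in trait table")
    return means


def _effective_lengths(tree: Phylogeny) -> dict[int, float]:
    """Branch lengths with zero-length branches perturbed to keep the
    weighted system finite."""
    eps = _ZERO_BRANCH_EPS * max(tree.height, 1.0)
    out = {}
    n_zero = 0
    for child, v in tree.branch_length.items():
        if v <= 0:
            out[child] = eps
            n_zero += 1
        else:
            out[child] = float(v)
    if n_zero:
        msg = f"{n_zero} zero-length branch(es) perturbed by eps={eps:.3g}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
    return out


def _tip_covariance(tree: Phylogeny, lengths: dict[int, float]) -> np.ndarray:
    """Shared-path-length matrix C among tips under BM from the root."""
    tips = tree.tips
    n = len(tips)
    # path to root for each tip as a dict of node -> cumulative depth
    anc_depth: list[dict[int, float]] = []
    depth: dict[int, float] = {tree.root: 0.0}
    kids = tree.children()
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in kids.get(node, []):
            depth[child] = depth[node] + lengths[child]
            stack.append(child)
    for tip in tips:
        path = {}
        node = tip
        while node != tree.root:
            node = tree.parent[node]
            path[node] = depth[node]
        anc_depth.append(path)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depth[tips[i]]
        for j in range(i + 1, n):
            shared = set(anc_depth[i]) & set(anc_depth[j])
            C[i, j] = C[j, i] = max(anc_depth[i][a] for a in shared)
    return C


def estimate_ancestral_states(tree: Phylogeny, means: pd.DataFrame) -> AncestralStates:
    """ML Brownian-motion ancestral estimates for every internal node.

    ``means`` is a taxon x trait matrix of tip means.  All traits are
    reconstructed independently under a single-rate BM model.
    """
    if not np.all(np.isfinite(means.to_numpy(dtype=float))):
        raise ValueError("non-finite tip means")
    missing = set(tree.tip_labels) - set(means.index)
    if missing:
        raise ValueError(f"tips without means: {sorted(missing)}")

    lengths = _effective_lengths(tree)
    tips = tree.tips
    internal = tree.internal_nodes
    node_pos = {node: k for k, node in enumerate(internal)}
    tip_pos = {node: k for k, node in enumerate(tips)}

    Y = means.loc[[tree.tip_label[t] for t in tips]].to_numpy(dtype=float)
    n_tips, p = Y.shape

    # Graph Laplacian with edge weights 1/v, partitioned internal|tips.
    L_II = np.zeros((len(internal), len(internal)))
    L_IT = np.zeros((len(internal), n_tips))
    for child, anc in tree.parent.items():
        w = 1.0 / lengths[child]
        ai = node_pos[anc]
        L_II[ai, ai] += w
        if child in tree.tip_label:
            L_IT[ai, tip_pos[child]] -= w
        else:
            ci = node_pos[child]
            L_II[ci, ci] += w
            L_II[ai, ci] -= w
            L_II[ci, ai] -= w

    try:
        X = np.linalg.solve(L_II, -L_IT @ Y)
        L_II_inv = np.linalg.inv(L_II)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular ancestral system: {exc}") from exc

    # Per-trait ML BM rate from the tip likelihood (GLS root, divisor n).
    C = _tip_covariance(tree, lengths)
    Cinv = np.linalg.inv(C)
    one = np.ones(n_tips)
    denom = one @ Cinv @ one
    mu = (one @ Cinv @ Y) / denom  # GLS root mean per trait
    resid = Y - np.outer(one, mu)
    sigma2 = np.einsum("ik,ij,jk->k", resid, Cinv, resid) / n_tips

    cond_var = np.maximum(np.diag(L_II_inv), 0.0)  # per-node, unit rate
    half = 1.959963984540054 * np.sqrt(np.outer(cond_var, sigma2))

    cols = list(means.columns)
    est = pd.DataFrame(X, index=internal, columns=cols)
    return AncestralStates(
        estimate=est,
        ci_lower=pd.DataFrame(X - half, index=internal, columns=cols),
        ci_upper=pd.DataFrame(X + half, index=internal, columns=cols),
        sigma2=pd.Series(sigma2, index=cols),
    )
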