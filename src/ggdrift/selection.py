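"""Retrospective selection-gradient reconstruction on flagged branches.

beta = W^-1 (z_descendant - z_ancestor) gives the differential selection
gradient that would produce the observed mean change in one step of the
multivariate breeder's equation.  Significance comes from a specimen-level
bootstrap of the descendant taxon's mean vector; traits are classified as
under direct selection (significant gradient whose sign matches the
realized response), indirect selection (signs oppose), or none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TraitTable

__all__ = [
    "SelectionResult",
    "selection_gradient",
    "bootstrap_gradient_ci",
    "response_pct",
    "classify_selection",
    "analyze_branch_selection",
    "selection_report",
]


@dataclass(frozen=True)
class SelectionResult:
    trait_name: str
    beta: float
    ci_lower: float
    ci_upper: float
    response_pct: float
    significant: bool
    classification: str

    def __post_init__(self):
        if self.ci_lower > self.ci_upper:
            raise ValueError("CI bounds out of order")
        excludes_zero = not (self.ci_lower <= 0.0 <= self.ci_upper)
        if self.significant != excludes_zero:
            raise ValueError("significant flag must mirror CI excluding zero")
        if (self.classification == "none") != (not self.significant):
            raise ValueError("classification 'none' iff not significant")


def selection_gradient(z_anc: np.ndarray, z_desc: np.ndarray, W_inv: np.ndarray) -> np.ndarray:
    """W^-1 applied to the descendant-minus-ancestor mean difference."""
    z_anc = np.asarray(z_anc, dtype=float)
    z_desc = np.asarray(z_desc, dtype=float)
    W_inv = np.asarray(W_inv, dtype=float)
    if z_anc.shape != z_desc.shape or W_inv.shape != (z_anc.size, z_anc.size):
        raise ValueError("dimension mismatch")
    return W_inv @ (z_desc - z_anc)


def bootstrap_gradient_ci(
    traits: TraitTable,
    taxon: str,
    z_anc: np.ndarray,
    W_inv: np.ndarray,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> np.ndarray:
    """Percentile CI of the per-trait gradient from B specimen resamples.

    Specimens of the descendant ``taxon`` are resampled with replacement,
    the resampled mean vector is turned into a gradient against the fixed
    ancestral estimate, and per-trait percentile bounds of the B gradients
    are returned as a (p, 2) array.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    mask = np.array([t == taxon for t in traits.taxon])
    Z = traits.z[mask]
    n = Z.shape[0]
    if n < 2:
        raise ValueError(f"taxon {taxon!r} has {n} specimens; need >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boot_means = Z[idx].mean(axis=1)  # (B, p)
    betas = (boot_means - np.asarray(z_anc, dtype=float)) @ np.asarray(W_inv, dtype=float).T
    lo_q = (1 - ci_level) / 2
    return np.quantile(betas, [lo_q, 1 - lo_q], axis=0).T


def response_pct(z_anc: float, z_desc: float, scale: str = "geometric") -> float:
    """Realized % change in the trait mean along the branch.

    ``geometric`` back-transforms from logs: 100*(e^zd - e^za)/e^za;
    ``logged`` reports the % change of the logged value itself.
    """
    if not (math.isfinite(z_anc) and math.isfinite(z_desc)):
        raise ValueError("non-finite inputs")
    if scale == "geometric":
        return 100.0 * math.expm1(z_desc - z_anc)
    if scale == "logged":
        if z_anc == 0:
            raise ZeroDivisionError("z_anc = 0 under logged scale")
        return 100.0 * (z_desc - z_anc) / z_anc
    raise ValueError(f"unknown scale {scale!r}")


def classify_selection(beta: float, ci: tuple[float, float], response: float) -> str:
    """Direct/indirect/none from the CI and the sign agreement rule."""
    lo, hi = ci
    if lo > hi:
        raise ValueError("CI bounds out of order")
    if lo <= 0.0 <= hi:
        return "none"
    if beta > 0 and response > 0:
        return "direct_increase"
    if beta < 0 and response < 0:
        return "direct_decrease"
    return "indirect"


def analyze_branch_selection(
    traits: TraitTable,
    taxon: str,
    z_anc: np.ndarray,
    z_desc: np.ndarray,
    W_inv: np.ndarray,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    response_scale: str = "geometric",
) -> list[SelectionResult]:
    """Full per-trait selection analysis for one ancestor->tip branch."""
    beta = selection_gradient(z_anc, z_desc, W_inv)
    ci = bootstrap_gradient_ci(traits, taxon, z_anc, W_inv, B=B, seed=seed)
    out = []
    for k, name in enumerate(traits.trait_names):
        resp = response_pct(float(z_anc[k]), float(z_desc[k]), scale=response_scale)
        cls = classify_selection(float(beta[k]), (float(ci[k, 0]), float(ci[k, 1])), resp)
        out.append(
            SelectionResult(
                trait_name=name,
                beta=float(beta[k]),
                ci_lower=float(ci[k, 0]),
                ci_upper=float(ci[k, 1]),
                response_pct=resp,
                significant=cls != "none",
                classification=cls,
            )
        )
    return out


def selection_report(
    branch: tuple[str, str],
    results: list[SelectionResult],
    trait_groups: dict[str, list[str]] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Report sorted by descending beta within user-defined trait groups.

    ``trait_groups`` maps a group name to its member traits (e.g. cranial
    vs mandibular); ungrouped traits fall into "other".  Per-group counts
    of direct/indirect/none are attached as a ``summary`` attribute and
    appended as comment lines in the TSV.
    """
    by_name = {r.trait_name: r for r in results}
    groups = dict(trait_groups or {})
    grouped = set().union(*groups.values()) if groups else set()
    rest = [n for n in by_name if n not in grouped]
    if rest or not groups:
        groups.setdefault("other", rest or list(by_name))

    rows = []
    summary = {}
    for gname, members in groups.items():
        members = [m for m in members if m in by_name]
        if not members:
            continue
        sub = sorted((by_name[m] for m in members), key=lambda r: -r.beta)
        n_direct = sum(r.classification.startswith("direct") for r in sub)
        n_indirect = sum(r.classification == "indirect" for r in sub)
        n_none = sum(r.classification == "none" for r in sub)
        summary[gname] = {
            "n": len(sub),
            "direct": n_direct,
            "indirect": n_indirect,
            "none": n_none,
            "line": f"{n_direct}/{len(sub)} direct",
        }
        for r in sub:
            rows.append(
                {
                    "group": gname,
                    "trait": r.trait_name,
                    "beta": r.beta,
                    "ci_lower": r.ci_lower,
                    "ci_upper": r.ci_upper,
                    "response_pct": r.response_pct,
                    "significant": r.significant,
                    "classification": r.classification,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["branch"] = branch
    df.attrs["summary"] = summary
    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"# branch\t{branch[0]}\t{branch[1]}\n")
            for gname, s in summary.items():
                fh.write(f"# {gname}\t{s['line']}\t(indirect={s['indirect']}, none={s['none']})\n")
            df.to_csv(fh, sep="\t", index=False)
    return df
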