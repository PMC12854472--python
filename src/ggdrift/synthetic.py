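"""Synthetic data with known truth for every pipeline stage.

Taxon means evolve on a tree by additive multivariate-normal increments
with per-branch covariance (t/Ne) * G, so that the drift statistic
computed with the true G and the true Ne/t is chi-square(p) by
construction on neutral branches.  An optional deterministic shift
c * G * beta on one branch injects directional selection with a known
gradient.  Specimens are drawn around tip means with covariance P and a
two-level sex structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import covariance as cov
from .ancestral import estimate_ancestral_states, tip_means
from .io import AnalysisConfig, BranchParams, Phylogeny, TraitTable, ne_over_t, parse_newick
from .rates import branch_rates, classify_rate, mahalanobis_sq, scale_by_ne_t
from .selection import selection_gradient

__all__ = [
    "SimulationScenario",
    "default_scenario",
    "node_label",
    "simulate_drift_means",
    "simulate_specimens",
    "null_calibration_experiment",
    "recovery_experiment",
]

_DEFAULT_NEWICK = (
    "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
)


def node_label(tree: Phylogeny, node: int) -> str:
    """Stable node name: taxon label for tips, 'N<id>' for internal nodes."""
    return tree.tip_label.get(node, f"N{node}")


def compound_symmetric(p: int, variance: float = 1.0, covariance: float = 0.3) -> np.ndarray:
    M = np.full((p, p), covariance)
    np.fill_diagonal(M, variance)
    return M


@dataclass(frozen=True)
class SimulationScenario:
    tree: Phylogeny
    P_true: np.ndarray
    h2_true: float
    params: dict[str, BranchParams]  # keyed by ancestral node label
    n_per_taxon: int = 50
    sex_effect: np.ndarray | None = None
    selected_branch: str | None = None  # descendant node label
    beta_true: np.ndarray | None = None
    shift_scale: float = 0.0
    root_mean: np.ndarray | None = None
    rng_seed: int = 0

    def __post_init__(self):
        P = np.asarray(self.P_true, dtype=float)
        object.__setattr__(self, "P_true", P)
        eig = np.linalg.eigvalsh((P + P.T) / 2)
        if eig.min() < -1e-10:
            raise ValueError("P_true must be positive semi-definite")
        if not (0 < self.h2_true <= 1):
            raise ValueError("h2_true must lie in (0, 1]")
        if self.shift_scale < 0:
            raise ValueError("shift_scale must be >= 0")
        if self.selected_branch is not None:
            labels = {node_label(self.tree, n) for n in range(self.tree.n_nodes)}
            if self.selected_branch not in labels:
                raise ValueError(f"selected_branch {self.selected_branch!r} not in tree")

    @property
    def p(self) -> int:
        return self.P_true.shape[0]

    @property
    def G_true(self) -> np.ndarray:
        return self.h2_true * self.P_true

    def branch_t_over_ne(self, anc: int, which: str = "mean") -> float:
        return 1.0 / ne_over_t(self.params[node_label(self.tree, anc)], which)

    def with_(self, **kwargs) -> "SimulationScenario":
        return replace(self, **kwargs)


def default_scenario(
    seed: int = 0,
    n_tips: int = 8,
    p: int = 6,
    n_per_taxon: int = 50,
    t_over_ne: float = 1.0,
    selected_branch: str | None = None,
    beta_true: Sequence[float] | None = None,
    shift_scale: float = 0.0,
) -> SimulationScenario:
    """Small fixture: 8-tip balanced tree, compound-symmetric P, h2 = 0.4.

    Branch lengths equal t/Ne so reconstruction weights match the true
    drift variances; every ancestral node shares one parameter set with
    Ne = 10^4, generation length 25 y, divergence time Ne*25*t_over_ne y.
    """
    if n_tips != 8:
        raise ValueError("the default fixture tree has 8 tips")
    tree = parse_newick(_DEFAULT_NEWICK)
    ne = 1.0e4
    gen = 25.0
    params = {
        node_label(tree, n): BranchParams(
            node_id=node_label(tree, n),
            Ne_mean=ne,
            Ne_lower=0.5 * ne,
            Ne_upper=2.0 * ne,
            divergence_time=ne * gen * t_over_ne,
            generation_length=gen,
        )
        for n in tree.internal_nodes
    }
    # rescale branch lengths to the per-branch t/Ne
    blen = {c: t_over_ne for c in tree.branch_length}
    tree = Phylogeny(
        parent=tree.parent,
        branch_length=blen,
        tip_label=tree.tip_label,
        root=tree.root,
    )
    return SimulationScenario(
        tree=tree,
        P_true=compound_symmetric(p),
        h2_true=0.4,
        params=params,
        n_per_taxon=n_per_taxon,
        sex_effect=np.full(p, 0.25),
        selected_branch=selected_branch,
        beta_true=None if beta_true is None else np.asarray(beta_true, dtype=float),
        shift_scale=shift_scale,
        rng_seed=seed,
    )


def simulate_drift_means(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """True mean vectors at every node (index = node id, columns = traits).

    Each branch adds MVN(0, (t/Ne) * G) using the ancestral node's
    parameters; the selected branch also adds the deterministic response
    c * G * beta_true.
    """
    rng = rng or np.random.default_rng(scenario.rng_seed)
    tree = scenario.tree
    G = scenario.G_true
    p = scenario.p
    chol = np.linalg.cholesky(G + 1e-12 * np.eye(p))
    means: dict[int, np.ndarray] = {}
    root_mean = (
        np.zeros(p) if scenario.root_mean is None else np.asarray(scenario.root_mean, float)
    )
    means[tree.root] = root_mean
    for anc, child in tree.edges():
        t_ne = scenario.branch_t_over_ne(anc)
        step = np.sqrt(t_ne) * (chol @ rng.standard_normal(p))
        if (
            scenario.selected_branch is not None
            and node_label(tree, child) == scenario.selected_branch
            and scenario.shift_scale > 0
        ):
            step = step + scenario.shift_scale * (G @ scenario.beta_true)
        means[child] = means[anc] + step
    idx = sorted(means)
    cols = [f"trait_{k+1}" for k in range(p)]
    return pd.DataFrame(np.vstack([means[i] for i in idx]), index=idx, columns=cols)


def true_tip_means(scenario: SimulationScenario, node_means: pd.DataFrame) -> pd.DataFrame:
    """Taxon-indexed view of the tip rows of a node-mean matrix."""
    tree = scenario.tree
    rows = node_means.loc[tree.tips]
    rows.index = [tree.tip_label[t] for t in tree.tips]
    return rows.sort_index()


def simulate_specimens(
    tip_mean_matrix: pd.DataFrame,
    P_true: np.ndarray,
    n_per_taxon: int,
    sex_effect: np.ndarray | None = None,
    rng: np.random.Generator | int = 0,
) -> TraitTable:
    """Specimen-level MVN samples around each tip mean with sex structure.

    Half of each taxon's specimens are labelled F, half M; ``sex_effect``
    is added to the M group.
    """
    if n_per_taxon < 2:
        raise ValueError("n_per_taxon must be >= 2")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    P = np.asarray(P_true, dtype=float)
    p = P.shape[0]
    chol = np.linalg.cholesky(P + 1e-12 * np.eye(p))
    ids, taxa, sexes, blocks = [], [], [], []
    for taxon in tip_mean_matrix.index:
        mu = tip_mean_matrix.loc[taxon].to_numpy(dtype=float)
        Z = mu + rng.standard_normal((n_per_taxon, p)) @ chol.T
        half = n_per_taxon // 2
        sex = np.array(["F"] * half + ["M"] * (n_per_taxon - half))
        if sex_effect is not None:
            Z[sex == "M"] += np.asarray(sex_effect, dtype=float)
        ids.extend(f"{taxon}_{i+1:03d}" for i in range(n_per_taxon))
        taxa.extend([str(taxon)] * n_per_taxon)
        sexes.extend(sex.tolist())
        blocks.append(Z)
    return TraitTable(
        specimen_id=ids,
        taxon=taxa,
        sex=sexes,
        z=np.vstack(blocks),
        trait_names=list(tip_mean_matrix.columns),
    )


@dataclass(frozen=True)
class NullCalibration:
    """Observed rejection rates and raw GGD draws under the drift null."""

    rates: pd.DataFrame  # per branch: reject_a1, reject_a2, nominal levels
    ggd: np.ndarray  # (n_reps, n_branches)
    branches: list[tuple[str, str]]
    alpha_levels: tuple[float, float]


def null_calibration_experiment(
    scenario: SimulationScenario,
    n_reps: int = 500,
    rng: np.random.Generator | int | None = None,
    alpha_levels: tuple[float, float] = (0.05, 0.001),
    use_true_means: bool = True,
) -> NullCalibration:
    """Monte-Carlo check of the chi-square drift null on every branch.

    With true node means, the true G and the true Ne/t the statistic is
    exactly chi-square(p); ``use_true_means=False`` swaps in BM-
    reconstructed ancestors (empirical behaviour, recorded not asserted).
    """
    if scenario.shift_scale != 0:
        raise ValueError("null calibration requires a pure-drift scenario (c = 0)")
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(scenario.rng_seed if rng is None else rng)
    )
    tree = scenario.tree
    G_inv = np.linalg.inv(scenario.G_true)
    edges = tree.edges()
    p = scenario.p
    ggd_draws = np.empty((n_reps, len(edges)))
    for r in range(n_reps):
        node_means = simulate_drift_means(scenario, rng)
        if use_true_means:
            values = {n: node_means.loc[n].to_numpy(dtype=float) for n in node_means.index}
        else:
            anc = estimate_ancestral_states(tree, true_tip_means(scenario, node_means))
            values = {n: node_means.loc[n].to_numpy(dtype=float) for n in tree.tips}
            for n in tree.internal_nodes:
                values[n] = anc.vector(n)
        for b, (a, c) in enumerate(edges):
            d2 = mahalanobis_sq(values[a], values[c], G_inv)
            ne_t = 1.0 / scenario.branch_t_over_ne(a)
            ggd_draws[r, b] = scale_by_ne_t(d2, ne_t)
    a1, a2 = alpha_levels
    q1 = stats.chi2.ppf([a1, 1 - a1], p)
    q2 = stats.chi2.ppf([a2, 1 - a2], p)
    rej1 = ((ggd_draws < q1[0]) | (ggd_draws > q1[1])).mean(axis=0)
    rej2 = ((ggd_draws < q2[0]) | (ggd_draws > q2[1])).mean(axis=0)
    branches = [(node_label(tree, a), node_label(tree, c)) for a, c in edges]
    rates = pd.DataFrame(
        {
            "ancestor": [b[0] for b in branches],
            "descendant": [b[1] for b in branches],
            "reject_a1": rej1,
            "reject_a2": rej2,
            "nominal_a1": 2 * a1,
            "nominal_a2": 2 * a2,
        }
    )
    return NullCalibration(rates=rates, ggd=ggd_draws, branches=branches, alpha_levels=alpha_levels)


def _pipeline_once(
    scenario: SimulationScenario,
    rng: np.random.Generator,
    config: AnalysisConfig,
):
    """One synthetic dataset pushed through the estimation pipeline."""
    node_means = simulate_drift_means(scenario, rng)
    traits = simulate_specimens(
        true_tip_means(scenario, node_means),
        scenario.P_true,
        scenario.n_per_taxon,
        scenario.sex_effect,
        rng,
    )
    means = tip_means(traits)
    anc = estimate_ancestral_states(scenario.tree, means)

    w_cache: dict[tuple[str, ...], np.ndarray] = {}

    def w_inv_for_branch(a: int, c: int) -> np.ndarray:
        if config.covariance_pooling_rule == "all":
            taxa = tuple(traits.taxa)
        else:
            taxa = tuple(cov.descendant_taxa(scenario.tree, a))
        if taxa not in w_cache:
            W = cov.pooled_w_for_taxa(
                traits, list(taxa), h2=config.heritability, divisor=config.cov_divisor
            )
            w_cache[taxa] = cov.invert_w(W)[0]
        return w_cache[taxa]

    results = branch_rates(
        scenario.tree,
        anc,
        means,
        w_inv_for_branch,
        scenario.params,
        config,
        node_name=lambda n: node_label(scenario.tree, n),
    )
    return node_means, traits, means, anc, results, w_inv_for_branch


def bootstrap_coverage_experiment(
    n_replicates: int = 500,
    B: int = 500,
    n_per_taxon: int = 50,
    p: int = 6,
    h2: float = 0.4,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Coverage of the bootstrap gradient CI under a true zero gradient.

    Each replicate draws one taxon's specimens around a fixed known mean,
    estimates W from them, and checks per trait whether the 95% percentile
    CI of the gradient (against the true ancestral mean, so beta_true = 0)
    covers zero.  Returns a (n_replicates, p) boolean array; the pooled
    mean should sit near 0.95.
    """
    from .selection import bootstrap_gradient_ci

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tips = pd.DataFrame(
        np.zeros((1, p)), index=["A"], columns=[f"trait_{k+1}" for k in range(p)]
    )
    P = compound_symmetric(p)
    z_anc = np.zeros(p)
    covered = np.zeros((n_replicates, p), dtype=bool)
    for r in range(n_replicates):
        tt = simulate_specimens(tips, P, n_per_taxon, None, rng)
        W = cov.pooled_w_for_taxa(tt, ["A"], h2=h2)
        W_inv = cov.invert_w(W)[0]
        ci = bootstrap_gradient_ci(tt, "A", z_anc, W_inv, B=B, seed=rng)
        covered[r] = (ci[:, 0] <= 0.0) & (0.0 <= ci[:, 1])
    return covered


@dataclass(frozen=True)
class RecoverySummary:
    power: float  # fraction of reps flagging the selected branch fast/very_fast
    sign_agreement: float  # mean sign match on above-noise-floor traits
    beta_correlation: float  # mean Pearson corr(beta_hat, beta_true)
    flagged: np.ndarray
    correlations: np.ndarray


def recovery_experiment(
    scenario: SimulationScenario,
    n_reps: int = 200,
    rng: np.random.Generator | int | None = None,
    config: AnalysisConfig | None = None,
    noise_floor: float = 0.0,
) -> RecoverySummary:
    """Power to flag the selected branch and fidelity of the recovered
    gradient over full-pipeline replicates (specimens -> W -> ancestors ->
    rates -> beta)."""
    if scenario.selected_branch is None or scenario.beta_true is None:
        raise ValueError("scenario must define selected_branch and beta_true")
    config = config or AnalysisConfig(heritability=scenario.h2_true)
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(scenario.rng_seed if rng is None else rng)
    )
    tree = scenario.tree
    beta_true = scenario.beta_true
    active = np.abs(beta_true) > noise_floor
    flagged = np.zeros(n_reps, dtype=bool)
    signs = np.empty(n_reps)
    corrs = np.empty(n_reps)
    for r in range(n_reps):
        _, traits, means, anc, results, w_inv_fn = _pipeline_once(scenario, rng, config)
        target = next(
            res
            for res in results
            if res.descendant == scenario.selected_branch
        )
        flagged[r] = target.regime["mean"] in ("fast", "very_fast")
        a = tree.tip_for_label(scenario.selected_branch) if scenario.selected_branch in tree.tip_labels else None
        anc_id = (
            tree.parent[a]
            if a is not None
            else next(n for n in tree.internal_nodes if node_label(tree, n) == target.ancestor)
        )
        z_anc = anc.vector(anc_id)
        if a is not None:
            z_desc = means.loc[scenario.selected_branch].to_numpy(dtype=float)
            child_id = a
        else:
            child_id = next(
                n for n in tree.internal_nodes if node_label(tree, n) == scenario.selected_branch
            )
            z_desc = anc.vector(child_id)
        beta_hat = selection_gradient(z_anc, z_desc, w_inv_fn(anc_id, child_id))
        signs[r] = np.mean(np.sign(beta_hat[active]) == np.sign(beta_true[active]))
        corrs[r] = np.corrcoef(beta_hat, beta_true)[0, 1]
    return RecoverySummary(
        power=float(flagged.mean()),
        sign_agreement=float(signs.mean()),
        beta_correlation=float(corrs.mean()),
        flagged=flagged,
        correlations=corrs,
    )
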