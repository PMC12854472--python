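"""End-to-end orchestration: traits + tree + demographic params -> reports.

Stage order: tip means -> ancestral reconstruction -> per-branch drift
test -> selection gradients on branches flagged fast/very-fast under the
mean-Ne scenario (overridable).  Every run writes ancestral.tsv,
rates.tsv, gradients.tsv and a manifest.json recording inputs, config
hash, seed, timings and all warnings raised along the way.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import covariance as cov
from .ancestral import estimate_ancestral_states, tip_means
from .io import AnalysisConfig, Phylogeny, read_branch_params, read_phylogeny, read_trait_table
from .rates import branch_rates, rates_table
from .selection import analyze_branch_selection, selection_report

__all__ = ["run_pipeline", "display_name"]


def display_name(tree: Phylogeny, node: int) -> str:
    """Name a node: tip label, Newick internal label, or 'N<id>'."""
    if node in tree.tip_label:
        return tree.tip_label[node]
    return tree.node_label.get(node, f"N{node}")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    for key in ("tree", "traits", "params"):
        if key not in raw:
            raise ValueError(f"config missing required key {key!r}")
    return raw


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Run all stages from a YAML config; returns the manifest dict."""
    t0 = time.perf_counter()
    cfg_path = Path(config_path)
    raw = _load_config(cfg_path)
    analysis = AnalysisConfig(**{
        k: (tuple(v) if k == "alpha_levels" else v)
        for k, v in (raw.get("analysis") or {}).items()
    })
    out = Path(out_dir or raw.get("output", "ggdrift_out"))
    out.mkdir(parents=True, exist_ok=True)
    all_branches = bool(raw.get("all_branches", False))

    timings: dict[str, float] = {}
    caught: list[str] = []

    def stage(name):
        def wrap(fn):
            start = time.perf_counter()
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                try:
                    result = fn()
                except Exception as exc:
                    raise PipelineError(name, exc) from exc
            caught.extend(f"{name}: {w.message}" for w in wlist)
            timings[name] = time.perf_counter() - start
            return result

        return wrap

    @stage("load")
    def loaded():
        tree = read_phylogeny(raw["tree"])
        traits = read_trait_table(
            raw["traits"],
            log_transform=bool(raw.get("log_transform", False)),
            log_base=analysis.log_base,
        )
        traits.validate_against_tree(tree)
        params = read_branch_params(raw["params"])
        return tree, traits, params

    tree, traits, params = loaded

    @stage("ancestral")
    def anc_result():
        means = tip_means(traits)
        anc = estimate_ancestral_states(tree, means)
        anc.to_tsv(out / "ancestral.tsv")
        return means, anc

    means, anc = anc_result

    w_cache: dict[tuple[str, ...], np.ndarray] = {}

    def w_inv_for_branch(a: int, c: int) -> np.ndarray:
        if analysis.covariance_pooling_rule == "all":
            taxa = tuple(traits.taxa)
        else:
            taxa = tuple(cov.descendant_taxa(tree, a))
        if taxa not in w_cache:
            W = cov.pooled_w_for_taxa(
                traits, list(taxa), h2=analysis.heritability, divisor=analysis.cov_divisor
            )
            w_cache[taxa] = cov.invert_w(W)[0]
        return w_cache[taxa]

    @stage("rates")
    def rate_results():
        results = branch_rates(
            tree, anc, means, w_inv_for_branch, params, analysis,
            node_name=lambda n: display_name(tree, n),
        )
        rates_table(results, out / "rates.tsv")
        return results

    results = rate_results

    @stage("gradients")
    def gradient_rows():
        flagged = [
            r for r in results
            if all_branches or r.regime["mean"] in ("fast", "very_fast")
        ]
        frames = []
        tip_by_label = {lab: n for n, lab in tree.tip_label.items()}
        for r in flagged:
            if r.descendant not in tip_by_label:
                warnings.warn(
                    f"branch {r.ancestor}->{r.descendant} flagged but descendant is "
                    "internal; gradient bootstrap needs specimens, skipping",
                    RuntimeWarning,
                )
                continue
            child = tip_by_label[r.descendant]
            anc_id = tree.parent[child]
            res = analyze_branch_selection(
                traits,
                r.descendant,
                anc.vector(anc_id),
                means.loc[r.descendant].to_numpy(dtype=float),
                w_inv_for_branch(anc_id, child),
                B=analysis.bootstrap_reps,
                seed=np.random.default_rng(analysis.rng_seed),
            )
            frames.append(((r.ancestor, r.descendant), res))
        with open(out / "gradients.tsv", "w") as fh:
            header = (
                "ancestor\tdescendant\ttrait\tbeta\tci_lower\tci_upper\t"
                "response_pct\tsignificant\tclassification\n"
            )
            fh.write(header)
            for (a, d), res in frames:
                for s in res:
                    fh.write(
                        f"{a}\t{d}\t{s.trait_name}\t{s.beta:.10g}\t{s.ci_lower:.10g}\t"
                        f"{s.ci_upper:.10g}\t{s.response_pct:.10g}\t{s.significant}\t"
                        f"{s.classification}\n"
                    )
        return frames

    _ = gradient_rows

    manifest = {
        "inputs": {k: str(raw[k]) for k in ("tree", "traits", "params")},
        "config_hash": hashlib.sha256(cfg_path.read_bytes()).hexdigest(),
        "seed": analysis.rng_seed,
        "version": __version__,
        "outputs": ["ancestral.tsv", "rates.tsv", "gradients.tsv", "manifest.json"],
        "timings_s": {k: round(v, 6) for k, v in timings.items()},
        "total_s": round(time.perf_counter() - t0, 6),
        "warnings": caught,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
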