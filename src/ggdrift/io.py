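"""Input handling and the shared data model.

Trees are read from Newick (via :mod:`dendropy`) into a light immutable
:class:`Phylogeny`; specimen-level trait tables from delimited text into a
:class:`TraitTable`; per-node demographic parameters into
:class:`BranchParams`.  Everything downstream consumes these three types
plus an :class:`AnalysisConfig`.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Phylogeny",
    "TraitTable",
    "BranchParams",
    "AnalysisConfig",
    "PhylogenyError",
    "TraitTableError",
    "read_phylogeny",
    "parse_newick",
    "read_trait_table",
    "read_branch_params",
    "ne_over_t",
]


class PhylogenyError(ValueError):
    """Raised for malformed or invalid tree input."""


class TraitTableError(ValueError):
    """Raised for malformed or invalid trait-table input."""


@dataclass(frozen=True)
class Phylogeny:
    """A rooted tree with branch lengths.

    Nodes are integer ids ``0..n_nodes-1``; tips carry taxon labels.
    ``parent[child] == ancestor`` for every non-root node and
    ``branch_length[child]`` is the length of the branch subtending
    ``child``.
    """

    parent: Mapping[int, int]
    branch_length: Mapping[int, float]
    tip_label: Mapping[int, str]
    root: int
    node_label: Mapping[int, str] = field(default_factory=dict)

    # -- structure -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent) + 1

    @property
    def tips(self) -> list[int]:
        return sorted(self.tip_label)

    @property
    def tip_labels(self) -> list[str]:
        return [self.tip_label[t] for t in self.tips]

    @property
    def internal_nodes(self) -> list[int]:
        """Internal node ids in preorder from the root (stable)."""
        kids = self.children()
        out: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in self.tip_label:
                continue
            out.append(node)
            stack.extend(reversed(kids.get(node, [])))
        return out

    def children(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {}
        for child in sorted(self.parent):
            kids.setdefault(self.parent[child], []).append(child)
        return kids

    def edges(self) -> list[tuple[int, int]]:
        """(ancestor, descendant) pairs, preorder by ancestor."""
        kids = self.children()
        out = []
        for anc in self.internal_nodes:
            for child in kids.get(anc, []):
                out.append((anc, child))
        return out

    def tip_for_label(self, label: str) -> int:
        for node, lab in self.tip_label.items():
            if lab == label:
                return node
        raise KeyError(label)

    def depths(self) -> dict[int, float]:
        """Path length from the root to every node."""
        kids = self.children()
        depth = {self.root: 0.0}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in kids.get(node, []):
                depth[child] = depth[node] + self.branch_length[child]
                stack.append(child)
        return depth

    @property
    def height(self) -> float:
        return max(self.depths().values())

    # -- validation ------------------------------------------------------

    def validate(self, allow_polytomies: bool = False) -> None:
        if len(set(self.tip_label.values())) != len(self.tip_label):
            raise PhylogenyError("duplicate tip labels")
        for child, length in self.branch_length.items():
            if not math.isfinite(length) or length < 0:
                raise PhylogenyError(f"invalid branch length {length!r} on node {child}")
        kids = self.children()
        reachable = set(self.depths())
        if len(reachable) != self.n_nodes:
            raise PhylogenyError("tree is not connected from the root")
        if not allow_polytomies:
            for node, cc in kids.items():
                if len(cc) != 2:
                    raise PhylogenyError(
                        f"node {node} has {len(cc)} children; tree must be fully resolved"
                    )

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        kids = self.children()

        def render(node: int) -> str:
            if node in self.tip_label:
                name = self.tip_label[node]
            else:
                inner = ",".join(render(c) for c in kids[node])
                name = f"({inner}){self.node_label.get(node, '')}"
            if node == self.root:
                return name
            return f"{name}:{self.branch_length[node]:.10g}"

        return render(self.root) + ";"


def _from_dendropy(tree: dendropy.Tree, allow_polytomies: bool) -> Phylogeny:
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent: dict[int, int] = {}
    blen: dict[int, float] = {}
    tip_label: dict[int, str] = {}
    node_label: dict[int, str] = {}
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise PhylogenyError("missing branch length")
            parent[i] = index[id(nd.parent_node)]
            blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise PhylogenyError("unlabeled tip")
            tip_label[i] = nd.taxon.label
        elif nd.label:
            node_label[i] = str(nd.label)
    phy = Phylogeny(
        parent=parent,
        branch_length=blen,
        tip_label=tip_label,
        root=index[id(tree.seed_node)],
        node_label=node_label,
    )
    phy.validate(allow_polytomies=allow_polytomies)
    return phy


def parse_newick(newick: str, allow_polytomies: bool = False) -> Phylogeny:
    """Parse a Newick string (branch lengths required on all edges)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"unparseable Newick: {exc}") from exc
    return _from_dendropy(tree, allow_polytomies)


def read_phylogeny(path: str | Path, allow_polytomies: bool = False) -> Phylogeny:
    """Read a rooted tree with branch lengths from a Newick file."""
    return parse_newick(Path(path).read_text(), allow_polytomies=allow_polytomies)


@dataclass(frozen=True)
class TraitTable:
    """Specimen-level observations: taxon, sex, and p trait values."""

    specimen_id: Sequence[str]
    taxon: Sequence[str]
    sex: Sequence[str]
    z: np.ndarray  # (n_specimens, p)
    trait_names: Sequence[str]

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        n = len(self.specimen_id)
        if not (len(self.taxon) == len(self.sex) == z.shape[0] == n):
            raise TraitTableError("inconsistent row counts")
        if z.shape[1] != len(self.trait_names):
            raise TraitTableError("trait_names length does not match data width")
        if not np.all(np.isfinite(z)):
            raise TraitTableError("non-finite trait values")
        if len(set(self.sex)) > 2:
            raise TraitTableError("sex must be a two-level factor")

    @property
    def n_specimens(self) -> int:
        return self.z.shape[0]

    @property
    def p(self) -> int:
        return self.z.shape[1]

    @property
    def taxa(self) -> list[str]:
        return sorted(set(self.taxon))

    def subset_taxa(self, taxa: Iterable[str]) -> "TraitTable":
        keep = set(taxa)
        missing = keep - set(self.taxon)
        if missing:
            raise TraitTableError(f"taxa not present in table: {sorted(missing)}")
        mask = np.array([t in keep for t in self.taxon])
        return TraitTable(
            specimen_id=[s for s, m in zip(self.specimen_id, mask) if m],
            taxon=[t for t, m in zip(self.taxon, mask) if m],
            sex=[s for s, m in zip(self.sex, mask) if m],
            z=self.z[mask],
            trait_names=list(self.trait_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.z, columns=list(self.trait_names))
        df.insert(0, "sex", list(self.sex))
        df.insert(0, "taxon", list(self.taxon))
        df.insert(0, "specimen_id", list(self.specimen_id))
        return df

    def validate_against_tree(self, tree: Phylogeny) -> None:
        unknown = set(self.taxon) - set(tree.tip_labels)
        if unknown:
            raise TraitTableError(
                f"taxa absent from the tree: {sorted(unknown)}"
            )


def read_trait_table(
    path: str | Path | _io.StringIO,
    log_transform: bool = False,
    log_base: str = "e",
    sep: str | None = None,
) -> TraitTable:
    """Read a delimited specimen table: specimen_id, taxon, sex, trait columns.

    With ``log_transform`` the raw measurements must be strictly positive and
    are logged element-wise (natural log by default, base 10 with
    ``log_base="10"``).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.shape[1] < 4:
        raise TraitTableError("expected specimen_id, taxon, sex plus >=1 trait column")
    ids, taxa, sexes = (df.iloc[:, i].astype(str) for i in range(3))
    traits = df.iloc[:, 3:]
    if traits.isna().any().any():
        raise TraitTableError("missing trait values")
    z = traits.to_numpy(dtype=float)
    if log_transform:
        if np.any(z <= 0):
            raise TraitTableError("non-positive measurement under log transform")
        z = np.log(z) if log_base == "e" else np.log10(z)
    return TraitTable(
        specimen_id=list(ids),
        taxon=list(taxa),
        sex=list(sexes),
        z=z,
        trait_names=[str(c) for c in traits.columns],
    )


@dataclass(frozen=True)
class BranchParams:
    """Demographic parameters attached to a branch's ancestral node.

    ``divergence_time`` and ``generation_length`` are in years; dividing
    them gives t, the number of generations since divergence.
    """

    node_id: str
    Ne_mean: float
    Ne_lower: float
    Ne_upper: float
    divergence_time: float
    generation_length: float

    def __post_init__(self):
        if not (0 < self.Ne_lower <= self.Ne_mean <= self.Ne_upper):
            raise ValueError(
                f"require 0 < Ne_lower <= Ne_mean <= Ne_upper, got "
                f"({self.Ne_lower}, {self.Ne_mean}, {self.Ne_upper})"
            )
        if self.divergence_time <= 0:
            raise ValueError("divergence_time must be > 0")
        if self.generation_length <= 0:
            raise ValueError("generation_length must be > 0")

    @property
    def generations(self) -> float:
        return self.divergence_time / self.generation_length


def ne_over_t(params: BranchParams, which: str = "mean") -> float:
    """Ne/t for the given Ne scenario, t in generations."""
    ne = {
        "mean": params.Ne_mean,
        "lower": params.Ne_lower,
        "upper": params.Ne_upper,
    }[which]
    return ne / params.generations


def read_branch_params(path: str | Path | _io.StringIO, sep: str | None = None) -> dict[str, BranchParams]:
    """Read per-node demographic parameters from a delimited table.

    Columns: node_id, Ne_mean, Ne_lower, Ne_upper, divergence_time,
    generation_length.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"node_id", "Ne_mean", "Ne_lower", "Ne_upper", "divergence_time", "generation_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: dict[str, BranchParams] = {}
    for _, row in df.iterrows():
        node = str(row["node_id"])
        out[node] = BranchParams(
            node_id=node,
            Ne_mean=float(row["Ne_mean"]),
            Ne_lower=float(row["Ne_lower"]),
            Ne_upper=float(row["Ne_upper"]),
            divergence_time=float(row["divergence_time"]),
            generation_length=float(row["generation_length"]),
        )
    return out


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-level settings shared by the pipeline stages."""

    heritability: float = 0.4
    bootstrap_reps: int = 1000
    alpha_levels: tuple[float, float] = (0.05, 0.001)
    rng_seed: int = 0
    covariance_pooling_rule: str = "descendants"  # or "all"
    tail_convention: str = "direct"  # quantiles {a,1-a}; "halved" uses {a/2,1-a/2}
    log_base: str = "e"
    cov_divisor: str = "n_minus_g"  # or "n"

    def __post_init__(self):
        if not (0 < self.heritability <= 1):
            raise ValueError("heritability must lie in (0, 1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        a1, a2 = self.alpha_levels
        if not (0 < a2 < a1 < 0.5):
            raise ValueError("alpha levels must satisfy 0 < a2 < a1 < 0.5")
        if self.covariance_pooling_rule not in ("descendants", "all"):
            raise ValueError("covariance_pooling_rule must be 'descendants' or 'all'")
        if self.tail_convention not in ("direct", "halved"):
            raise ValueError("tail_convention must be 'direct' or 'halved'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "alpha_levels" in raw:
            raw["alpha_levels"] = tuple(raw["alpha_levels"])
        return cls(**raw)

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
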