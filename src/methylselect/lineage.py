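"""Cell-lineage inference and lineage-derived candidate partition models.

Blood cell types are related through the hematopoietic differentiation
hierarchy: cell types that diverged recently share more of their methylome
than distant ones.  The lineage is recovered here by agglomerative
clustering of per-cell-type mean methylation profiles, and every internal
node of the resulting dendrogram proposes a candidate methylation
"pattern": the cell types under the node each receive their own mean level
while all remaining cell types are pooled into a single *reference*
partition.  Together with the null model (one common mean for every cell
type) and the saturated model (every cell type its own mean) these
partitions form the model space over which per-CpG Bayesian model
selection operates.

A candidate model is therefore nothing more than a set partition of the
cell-type labels plus a distinguished reference group; its design matrix
is the one-hot group-membership encoding used by the linear model in
:mod:`methylselect.bayes`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "LineageTree",
    "CandidateModel",
    "ModelSet",
    "cell_type_means",
    "infer_lineage",
    "enumerate_candidate_models",
    "hematopoietic_tree",
    "hematopoietic_model_set",
    "DEFAULT_CELL_TYPES",
]

#: Supported agglomeration criteria, mapped onto scipy's names.
#: "wpgma" is scipy's "weighted" method (McQuitty).
LINKAGE_METHODS = {
    "complete": "complete",
    "single": "single",
    "upgma": "average",
    "wpgma": "weighted",
}

#: Cell-type labels of the six-population sorted-leukocyte design the
#: default simulator emulates.
DEFAULT_CELL_TYPES = ("CD14Mono", "CD16Neu", "CD19B", "CD4T", "CD56NK", "CD8T")


@dataclass(frozen=True)
class LineageTree:
    """Rooted binary dendrogram over cell-type labels.

    Node ``j`` for ``j < J`` is leaf ``leaves[j]``; merge ``t`` creates
    internal node ``J + t``.  Heights are the linkage distances at which
    merges occur.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]
    linkage: str

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError(
                f"a binary tree over {len(self.leaves)} leaves requires "
                f"{len(self.leaves) - 1} merges, got {len(self.merges)}"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def node_height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def clade(self, node: int) -> frozenset[str]:
        """Leaf labels under ``node``."""
        if node < self.n_leaves:
            return frozenset((self.leaves[node],))
        left, right, _ = self.merges[node - self.n_leaves]
        return self.clade(left) | self.clade(right)

    def internal_clades(self, include_root: bool = True) -> list[frozenset[str]]:
        """Leaf sets of internal nodes, in merge order."""
        out = [self.clade(self.n_leaves + t) for t in range(len(self.merges))]
        return out if include_root else out[:-1]

    def to_newick(self) -> str:
        """Serialize with branch lengths = parent height − child height."""

        def fmt(node: int, parent_height: float) -> str:
            bl = parent_height - self.node_height(node)
            if node < self.n_leaves:
                return f"{self.leaves[node]}:{bl:.6g}"
            left, right, h = self.merges[node - self.n_leaves]
            return f"({fmt(left, h)},{fmt(right, h)}):{bl:.6g}"

        left, right, h = self.merges[-1]
        return f"({fmt(left, h)},{fmt(right, h)});"


def cell_type_means(dataset) -> pd.DataFrame:
    """Mean methylation per cell type (rows) and probe (columns).

    Averages the K × n × J tensor over subjects; this J × K profile matrix
    is the input to lineage inference.
    """
    means = dataset.beta.mean(axis=1)  # K × J
    return pd.DataFrame(
        means.T, index=list(dataset.cell_types), columns=list(dataset.probe_ids)
    )


def infer_lineage(means, linkage: str = "complete", cell_types=None) -> LineageTree:
    """Agglomerative clustering of cell-type mean profiles.

    Parameters
    ----------
    means
        J × K matrix of per-cell-type mean β-values; a DataFrame indexed by
        cell type, or an array with ``cell_types`` given separately.
    linkage
        One of ``complete``, ``single``, ``upgma``, ``wpgma``; distances
        are Euclidean throughout.

    Rows are sorted lexicographically by label before clustering so that
    distance ties are broken deterministically by the smallest member
    label.
    """
    if linkage not in LINKAGE_METHODS:
        raise ValueError(
            f"unknown linkage {linkage!r}; expected one of {sorted(LINKAGE_METHODS)}"
        )
    if isinstance(means, pd.DataFrame):
        labels = [str(x) for x in means.index]
        X = means.to_numpy(dtype=float)
    else:
        X = np.asarray(means, dtype=float)
        if cell_types is None:
            raise ValueError("cell_types required when means is a bare array")
        labels = [str(x) for x in cell_types]
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("means must be a J x K matrix with one row per cell type")
    if len(labels) < 2:
        raise ValueError("at least two cell types are required")

    order = np.argsort(labels, kind="stable")
    labels = [labels[i] for i in order]
    Z = hierarchy.linkage(X[order], method=LINKAGE_METHODS[linkage], metric="euclidean")
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    return LineageTree(leaves=tuple(labels), merges=merges, linkage=linkage)


@dataclass(frozen=True)
class CandidateModel:
    """A named set partition of the cell types with a reference group.

    ``partition`` lists disjoint, covering groups of cell-type labels;
    cell-specific groups come first and the pooled reference group (if
    any) last.  The null and saturated models carry no reference.
    ``design`` is the J × P one-hot membership matrix in ``cell_types``
    row order, so its Gram matrix is diag of the group sizes.
    """

    name: str
    cell_types: tuple[str, ...]
    partition: tuple[tuple[str, ...], ...]
    reference_index: int | None

    def __post_init__(self) -> None:
        flat = [ct for grp in self.partition for ct in grp]
        if sorted(flat) != sorted(self.cell_types) or len(set(flat)) != len(flat):
            raise ValueError(
                f"model {self.name!r}: partition must be disjoint groups covering "
                "all cell types"
            )
        if any(len(grp) == 0 for grp in self.partition):
            raise ValueError(f"model {self.name!r}: empty partition group")
        if self.reference_index is not None and not (
            0 <= self.reference_index < len(self.partition)
        ):
            raise ValueError(f"model {self.name!r}: reference_index out of range")

    @property
    def n_partitions(self) -> int:
        return len(self.partition)

    @property
    def partition_sizes(self) -> np.ndarray:
        return np.array([len(grp) for grp in self.partition], dtype=int)

    @property
    def design(self) -> np.ndarray:
        J, P = len(self.cell_types), self.n_partitions
        X = np.zeros((J, P))
        col = {ct: p for p, grp in enumerate(self.partition) for ct in grp}
        for j, ct in enumerate(self.cell_types):
            X[j, col[ct]] = 1.0
        return X

    @property
    def cell_specific_indices(self) -> tuple[int, ...]:
        """Indices of the non-reference (differentially methylated) groups.

        Empty for the null model; every group for the saturated model.
        """
        if self.reference_index is None:
            if self.n_partitions == 1:  # null
                return ()
            return tuple(range(self.n_partitions))  # saturated
        return tuple(
            p for p in range(self.n_partitions) if p != self.reference_index
        )

    def as_set_partition(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(grp) for grp in self.partition)

    def group_label(self, p: int) -> str:
        return ",".join(self.partition[p])

    def renamed(self, name: str) -> "CandidateModel":
        return CandidateModel(name, self.cell_types, self.partition, self.reference_index)


def _sorted_group(members) -> tuple[str, ...]:
    return tuple(sorted(members))


def model_from_groups(
    name: str,
    groups,
    cell_types,
    reference_index: int | None,
) -> CandidateModel:
    """Build a CandidateModel from raw label groups (order preserved)."""
    return CandidateModel(
        name=name,
        cell_types=tuple(sorted(cell_types)),
        partition=tuple(_sorted_group(g) for g in groups),
        reference_index=reference_index,
    )


@dataclass
class ModelSet:
    """Candidate models with their prior probabilities (equal by default)."""

    models: list[CandidateModel]
    prior: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.prior is None:
            self.prior = np.full(len(self.models), 1.0 / len(self.models))
        self.prior = np.asarray(self.prior, dtype=float)
        if len(self.prior) != len(self.models):
            raise ValueError("prior length must match number of models")
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("model prior must sum to 1")
        parts = [m.as_set_partition() for m in self.models]
        if len(set(parts)) != len(parts):
            raise ValueError("candidate models must have pairwise distinct partitions")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, key) -> CandidateModel:
        if isinstance(key, str):
            for m in self.models:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.models[key]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.models]

    def index(self, name: str) -> int:
        return self.names.index(name)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            groups = []
            for p, grp in enumerate(m.partition):
                s = ",".join(grp)
                if m.reference_index == p:
                    s += "*"
                groups.append(s)
            rows.append({"model": m.name, "partition": ";".join(groups)})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModelSet":
        models = []
        cell_types: set[str] = set()
        parsed = []
        for _, row in df.iterrows():
            groups, ref = [], None
            for p, token in enumerate(str(row["partition"]).split(";")):
                token = token.strip()
                if token.endswith("*"):
                    ref = p
                    token = token[:-1]
                groups.append(tuple(t.strip() for t in token.split(",")))
            parsed.append((str(row["model"]), groups, ref))
            cell_types.update(ct for g in groups for ct in g)
        for name, groups, ref in parsed:
            models.append(model_from_groups(name, groups, sorted(cell_types), ref))
        return cls(models=models)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ModelSet":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))


def enumerate_candidate_models(tree: LineageTree) -> ModelSet:
    """Enumerate the lineage-derived candidate models of a dendrogram.

    One single-cell model per leaf, one multi-cell model per internal
    non-root node (each member cell type gets its own mean, all
    non-members pooled into the reference group), plus the null and
    saturated models.  The root node is skipped: its model coincides with
    the saturated one.  Models whose set partitions coincide are
    deduplicated, keeping the earlier (more canonical) name — Null and
    All first, then leaf models, then node models in merge order — so the
    saturated model absorbs colliding node/leaf models.
    """
    cell_types = tuple(sorted(tree.leaves))
    all_set = set(cell_types)

    candidates: list[CandidateModel] = [
        model_from_groups("Null", [cell_types], cell_types, None),
        model_from_groups("All", [(ct,) for ct in cell_types], cell_types, None),
    ]
    for leaf in cell_types:
        rest = _sorted_group(all_set - {leaf})
        candidates.append(
            model_from_groups(leaf, [(leaf,), rest], cell_types, 1)
        )
    for members in tree.internal_clades(include_root=False):
        singles = [(ct,) for ct in sorted(members)]
        rest = _sorted_group(all_set - members)
        groups = singles + ([rest] if rest else [])
        ref = len(groups) - 1 if rest else None
        name = "+".join(sorted(members))
        candidates.append(model_from_groups(name, groups, cell_types, ref))

    seen: dict[frozenset, CandidateModel] = {}
    for m in candidates:
        seen.setdefault(m.as_set_partition(), m)
    return ModelSet(models=list(seen.values()))


def hematopoietic_tree(
    mono: str = "CD14Mono",
    neu: str = "CD16Neu",
    b: str = "CD19B",
    cd4: str = "CD4T",
    nk: str = "CD56NK",
    cd8: str = "CD8T",
) -> LineageTree:
    """The canonical six-population whole-blood lineage.

    Monocytes and neutrophils form the myeloid branch; on the lymphoid
    side the two T-cell populations pair first, NK cells join them, then
    B cells, and the root joins the two branches.  Heights are nominal.
    """
    leaves = (mono, neu, b, cd4, nk, cd8)
    merges = (
        (0, 1, 1.0),  # node 6: myeloid
        (3, 5, 1.0),  # node 7: pan T
        (7, 4, 2.0),  # node 8: T + NK
        (8, 2, 3.0),  # node 9: all lymphocytes
        (6, 9, 4.0),  # root
    )
    return LineageTree(leaves=leaves, merges=merges, linkage="complete")


def hematopoietic_model_set(tree: LineageTree | None = None) -> ModelSet:
    """The twelve-model candidate set of the six-population design.

    Enumerates the canonical lineage and applies the conventional model
    names: ``Myeloid`` (both myeloid populations differential),
    ``Pan T`` (both T-cell populations), ``Lymphocyte-II`` (T + NK) and
    ``Lymphocyte-I`` (all four lymphocyte populations); single-cell
    models keep their cell-type label.
    """
    tree = tree or hematopoietic_tree()
    mono, neu, b, cd4, nk, cd8 = tree.leaves
    names = {
        frozenset({mono, neu}): "Myeloid",
        frozenset({cd4, cd8}): "Pan T",
        frozenset({cd4, cd8, nk}): "Lymphocyte-II",
        frozenset({b, cd4, cd8, nk}): "Lymphocyte-I",
    }
    ms = enumerate_candidate_models(tree)
    renamed = []
    for m in ms.models:
        members = frozenset(
            ct for p in m.cell_specific_indices for ct in m.partition[p]
        )
        if m.reference_index is not None and members in names:
            renamed.append(m.renamed(names[members]))
        else:
            renamed.append(m)
    return ModelSet(models=renamed, prior=ms.prior)
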