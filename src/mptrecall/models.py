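"""Multinomial processing tree (MPT) models for recall data.

An MPT model expresses the probability of each observable response
category as a sum over tree branches, each branch being a product of
latent process probabilities or their complements.  Two models are
built in: the pair-clustering model for free recall of semantically
related word pairs plus singletons (parameters ``c``, ``r``, ``u_p``,
``u_s``) and the storage-retrieval model for free-then-cued recall of
cue-target pairs (parameters ``a``, ``r``, ``s``, ``u``, ``f``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "Branch",
    "Tree",
    "MPTModel",
    "PersonCounts",
    "build_pair_clustering_model",
    "build_storage_retrieval_model",
    "category_probabilities",
    "simulate_category_counts",
    "fit_aggregate_mle",
    "MPTValidationError",
]

Polarity = Literal["direct", "complement"]


class MPTValidationError(ValueError):
    """Raised when a model, parameter vector, or count table is malformed."""


@dataclass(frozen=True)
class Branch:
    """One processing path: a target category and ordered (param, polarity) factors.

    ``multiplicity`` collapses interchangeable paths (e.g. which pair member
    was the one recalled) into a single branch term like ``2*u*(1-u)``,
    matching how the trees are conventionally drawn.
    """

    category: str
    factors: tuple[tuple[str, Polarity], ...]
    multiplicity: int = 1

    def probability(self, params: Mapping[str, float]) -> float:
        p = float(self.multiplicity)
        for name, pol in self.factors:
            v = params[name]
            p *= v if pol == "direct" else 1.0 - v
        return p


@dataclass(frozen=True)
class Tree:
    """One multinomial sub-experiment (e.g. the pair tree or singleton tree)."""

    name: str
    item_total_role: str
    categories: tuple[str, ...]
    branches: tuple[Branch, ...]


@dataclass(frozen=True)
class MPTModel:
    name: str
    parameters: tuple[str, ...]
    trees: tuple[Tree, ...]

    def __post_init__(self) -> None:
        validate_model(self)

    @property
    def tree_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.trees)

    def tree(self, name: str) -> Tree:
        for t in self.trees:
            if t.name == name:
                return t
        raise KeyError(name)

    def structurally_equal(self, other: "MPTModel") -> bool:
        """Equality up to branch order and factor order within a branch."""
        if tuple(sorted(self.parameters)) != tuple(sorted(other.parameters)):
            return False
        if self.tree_names != other.tree_names:
            return False
        for ta, tb in zip(self.trees, other.trees):
            if ta.categories != tb.categories:
                return False
            key = lambda b: (b.category, b.multiplicity, tuple(sorted(b.factors)))
            if sorted((key(b) for b in ta.branches)) != sorted(
                (key(b) for b in tb.branches)
            ):
                return False
        return True


def validate_model(model: MPTModel) -> None:
    """Check structural invariants; raise :class:`MPTValidationError` on failure.

    Verified: every branch factor references a declared parameter; category
    labels are unique within a tree and every category is reached by at least
    one branch; branch probabilities within each tree sum to 1 (checked
    numerically to 1e-10 at random interior points, which catches any
    structural completeness error such as a missing branch).
    """
    declared = set(model.parameters)
    for tree in model.trees:
        if len(set(tree.categories)) != len(tree.categories):
            raise MPTValidationError(
                f"tree {tree.name!r}: duplicate category labels"
            )
        reached = {b.category for b in tree.branches}
        if not reached <= set(tree.categories):
            raise MPTValidationError(
                f"tree {tree.name!r}: branch targets unknown category "
                f"{sorted(reached - set(tree.categories))}"
            )
        if reached != set(tree.categories):
            raise MPTValidationError(
                f"tree {tree.name!r}: categories never reached: "
                f"{sorted(set(tree.categories) - reached)}"
            )
        for b in tree.branches:
            for name, pol in b.factors:
                if name not in declared:
                    raise MPTValidationError(
                        f"tree {tree.name!r}: undeclared parameter {name!r}"
                    )
                if pol not in ("direct", "complement"):
                    raise MPTValidationError(f"bad polarity {pol!r}")
    # numeric completeness check: branch sum must be 1 for any parameter values
    rng = np.random.default_rng(0)
    for _ in range(8):
        params = {p: float(rng.uniform(0.05, 0.95)) for p in model.parameters}
        for tree in model.trees:
            s = sum(b.probability(params) for b in tree.branches)
            if abs(s - 1.0) > 1e-10:
                raise MPTValidationError(
                    f"tree {tree.name!r}: branch sum != 1 (got {s:.12f} at a "
                    "random interior point); the tree is incomplete or "
                    "overcomplete"
                )


def build_pair_clustering_model() -> MPTModel:
    """Pair-clustering model for free recall of pairs plus singletons.

    Pair tree events: E1 both pair words recalled adjacently, E2 both
    recalled but separated, E3 exactly one recalled, E4 neither.  A pair
    is stored as a cluster with probability ``c`` and a stored cluster is
    retrieved with probability ``r`` (yielding adjacent recall of both
    words); unclustered words are individually stored-and-retrieved with
    probability ``u_p`` each.  Singletons (F1 recalled / F2 not) have
    their own storage-and-retrieval probability ``u_s``.
    """
    d, c_ = "direct", "complement"
    pair = Tree(
        name="pairs",
        item_total_role="pairs",
        categories=("E1", "E2", "E3", "E4"),
        branches=(
            Branch("E1", (("c", d), ("r", d))),
            Branch("E2", (("c", c_), ("u_p", d), ("u_p", d))),
            Branch("E3", (("c", c_), ("u_p", d), ("u_p", c_)), multiplicity=2),
            Branch("E4", (("c", d), ("r", c_))),
            Branch("E4", (("c", c_), ("u_p", c_), ("u_p", c_))),
        ),
    )
    single = Tree(
        name="singletons",
        item_total_role="singletons",
        categories=("F1", "F2"),
        branches=(
            Branch("F1", (("u_s", d),)),
            Branch("F2", (("u_s", c_),)),
        ),
    )
    return MPTModel(
        name="pair_clustering",
        parameters=("c", "r", "u_p", "u_s"),
        trees=(pair, single),
    )


def build_storage_retrieval_model() -> MPTModel:
    """Storage-retrieval model for free-then-cued recall of cue-target pairs.

    Six categories cross free recall of a pair (both / one / no word)
    with cued recall (correct / incorrect): C1 both+correct, C2
    both+incorrect, C3 one+correct, C4 one+incorrect, C5 none+correct,
    C6 none+incorrect.  ``a`` is associative storage, ``r`` associative
    retrieval at free recall, ``s`` single-word free retrieval of stored
    but unretrieved pairs, ``u`` single-word storage-and-retrieval of
    unstored pairs, and ``f`` forgetting of the stored association in
    the interval between the free and the cued test.  Forgetting applies
    only when associative free retrieval failed: a pair that was stored
    and freely retrieved as a pair is recalled correctly at the cued
    test unconditionally.
    """
    d, c_ = "direct", "complement"
    tree = Tree(
        name="pairs",
        item_total_role="pairs",
        categories=("C1", "C2", "C3", "C4", "C5", "C6"),
        branches=(
            Branch("C1", (("a", d), ("r", d))),
            Branch("C1", (("a", d), ("r", c_), ("f", c_), ("s", d), ("s", d))),
            Branch("C2", (("a", d), ("r", c_), ("f", d), ("s", d), ("s", d))),
            Branch("C2", (("a", c_), ("u", d), ("u", d))),
            Branch("C3", (("a", d), ("r", c_), ("f", c_), ("s", d), ("s", c_)), multiplicity=2),
            Branch("C4", (("a", d), ("r", c_), ("f", d), ("s", d), ("s", c_)), multiplicity=2),
            Branch("C4", (("a", c_), ("u", d), ("u", c_)), multiplicity=2),
            Branch("C5", (("a", d), ("r", c_), ("f", c_), ("s", c_), ("s", c_))),
            Branch("C6", (("a", d), ("r", c_), ("f", d), ("s", c_), ("s", c_))),
            Branch("C6", (("a", c_), ("u", c_), ("u", c_))),
        ),
    )
    return MPTModel(
        name="storage_retrieval",
        parameters=("a", "r", "s", "u", "f"),
        trees=(tree,),
    )


@dataclass(frozen=True)
class PersonCounts:
    """Per-participant category-frequency tables, one block per tree.

    ``tables[tree]`` is an (n_persons, K_tree) integer array aligned with
    the tree's category order; each row sums to that tree's item total.
    """

    person_ids: tuple[str, ...]
    tables: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.person_ids)
        if len(set(self.person_ids)) != n:
            raise MPTValidationError("person ids must be unique")
        for t, arr in self.tables.items():
            arr = np.asarray(arr)
            if arr.ndim != 2 or arr.shape[0] != n:
                raise MPTValidationError(
                    f"tree {t!r}: table must be (n_persons, K), got {arr.shape}"
                )
            if np.any(arr < 0):
                raise MPTValidationError(f"tree {t!r}: negative counts")
            totals = arr.sum(axis=1)
            if n and np.any(totals != totals[0]):
                raise MPTValidationError(
                    f"tree {t!r}: item totals differ across persons"
                )

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    def validate_for(self, model: MPTModel) -> None:
        for tree in model.trees:
            if tree.name not in self.tables:
                raise MPTValidationError(f"counts missing tree {tree.name!r}")
            if np.asarray(self.tables[tree.name]).shape[1] != len(tree.categories):
                raise MPTValidationError(
                    f"tree {tree.name!r}: category dimension mismatch"
                )

    def to_dataframe(self, model: MPTModel):
        import pandas as pd

        rows = []
        for tree in model.trees:
            arr = np.asarray(self.tables[tree.name])
            for i, pid in enumerate(self.person_ids):
                for k, cat in enumerate(tree.categories):
                    rows.append(
                        dict(person_id=pid, tree=tree.name, category=cat,
                             count=int(arr[i, k]))
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df, model: MPTModel) -> "PersonCounts":
        pids = tuple(dict.fromkeys(df["person_id"].astype(str)))
        pidx = {p: i for i, p in enumerate(pids)}
        tables = {}
        for tree in model.trees:
            sub = df[df["tree"] == tree.name]
            arr = np.zeros((len(pids), len(tree.categories)), dtype=int)
            cidx = {c: k for k, c in enumerate(tree.categories)}
            for _, row in sub.iterrows():
                arr[pidx[str(row["person_id"])], cidx[row["category"]]] = int(row["count"])
            tables[tree.name] = arr
        return cls(pids, tables)


def _check_params(model: MPTModel, params: Mapping[str, float]) -> None:
    keys = set(params)
    declared = set(model.parameters)
    if keys != declared:
        missing, extra = declared - keys, keys - declared
        raise MPTValidationError(
            f"parameter keys do not match model: missing={sorted(missing)}, "
            f"extra={sorted(extra)}"
        )
    for k, v in params.items():
        if not (0.0 < v < 1.0):
            raise MPTValidationError(
                f"parameter {k!r}={v} outside the open interval (0, 1)"
            )


def category_probabilities(
    model: MPTModel, params: Mapping[str, float]
) -> dict[str, np.ndarray]:
    """Evaluate per-tree category probability vectors at a parameter point.

    Returns a dict mapping tree name to a vector aligned with the tree's
    category order; each vector sums to 1.
    """
    _check_params(model, params)
    out: dict[str, np.ndarray] = {}
    for tree in model.trees:
        idx = {c: i for i, c in enumerate(tree.categories)}
        probs = np.zeros(len(tree.categories))
        for b in tree.branches:
            probs[idx[b.category]] += b.probability(params)
        out[tree.name] = probs
    return out


def category_probabilities_matrix(
    model: MPTModel, theta: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized category probabilities for many parameter points.

    ``theta`` has shape (n, P), columns ordered as ``model.parameters``.
    Returns tree name -> (n, K_tree) array.  No domain checks: internal
    fast path used by the samplers and simulators.
    """
    theta = np.atleast_2d(theta)
    pidx = {p: j for j, p in enumerate(model.parameters)}
    out: dict[str, np.ndarray] = {}
    for tree in model.trees:
        idx = {c: i for i, c in enumerate(tree.categories)}
        probs = np.zeros((theta.shape[0], len(tree.categories)))
        for b in tree.branches:
            term = np.full(theta.shape[0], float(b.multiplicity))
            for name, pol in b.factors:
                col = theta[:, pidx[name]]
                term = term * (col if pol == "direct" else 1.0 - col)
            probs[:, idx[b.category]] += term
        out[tree.name] = probs
    return out


def simulate_category_counts(
    model: MPTModel,
    params: Mapping[str, float],
    items_per_tree: Mapping[str, int],
    seed: int | np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw one multinomial count vector per tree; reproducible under seed."""
    for t, n in items_per_tree.items():
        if n <= 0 or int(n) != n:
            raise MPTValidationError(f"items for tree {t!r} must be a positive integer")
    probs = category_probabilities(model, params)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return {
        t: rng.multinomial(int(items_per_tree[t]), probs[t]) for t in model.tree_names
    }


def validate_counts(model: MPTModel, counts: Mapping[str, Sequence[int]]) -> None:
    for tree in model.trees:
        if tree.name not in counts:
            raise MPTValidationError(f"counts missing tree {tree.name!r}")
        vec = np.asarray(counts[tree.name])
        if vec.shape[-1] != len(tree.categories):
            raise MPTValidationError(
                f"tree {tree.name!r}: expected {len(tree.categories)} categories, "
                f"got {vec.shape[-1]}"
            )
        if np.any(vec < 0) or not np.issubdtype(vec.dtype, np.integer):
            raise MPTValidationError(f"tree {tree.name!r}: counts must be non-negative integers")


def _neg_loglik(x: np.ndarray, model: MPTModel, counts: Mapping[str, np.ndarray]) -> float:
    theta = expit(x)[None, :]
    probs = category_probabilities_matrix(model, theta)
    ll = 0.0
    for tree in model.trees:
        p = np.clip(probs[tree.name][0], 1e-300, None)
        ll += float(np.asarray(counts[tree.name], dtype=float) @ np.log(p))
    return -ll


def fit_aggregate_mle(
    model: MPTModel,
    counts: Mapping[str, Sequence[int]],
    n_starts: int = 7,
    seed: int = 0,
) -> dict[str, float]:
    """Maximum-likelihood estimates from aggregate category counts.

    Maximizes the product-multinomial likelihood by multi-start bounded
    quasi-Newton optimization on logit-transformed parameters, which keeps
    iterates away from the 0/1 boundary.  Serves as the non-hierarchical
    reference fitter.  Estimates are clipped into [1e-6, 1-1e-6]; boundary
    or degenerate data (a tree with zero total) trigger a warning.
    """
    validate_counts(model, counts)
    counts = {t: np.asarray(counts[t]) for t in model.tree_names}
    degenerate = any(counts[t].sum() == 0 for t in model.tree_names)
    if degenerate:
        warnings.warn("a tree has zero total count; estimates are weakly identified")

    P = len(model.parameters)
    rng = np.random.default_rng(seed)
    starts = [np.zeros(P)]  # all parameters at .5
    starts += [logit(rng.uniform(0.1, 0.9, size=P)) for _ in range(n_starts - 1)]
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            _neg_loglik,
            x0,
            args=(model, counts),
            method="L-BFGS-B",
            bounds=[(-16.0, 16.0)] * P,
            options=dict(ftol=1e-14, maxfun=50_000),
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    # derivative-free polish: with large counts the likelihood differences
    # that matter fall below finite-difference gradient precision
    res = minimize(
        _neg_loglik, best_x, args=(model, counts), method="Nelder-Mead",
        options=dict(xatol=1e-9, fatol=1e-10, maxiter=20_000, maxfev=20_000),
    )
    if res.fun < best_f:
        best_f, best_x = res.fun, res.x
    theta = np.clip(expit(best_x), 1e-6, 1 - 1e-6)
    if np.any(theta <= 1e-6) or np.any(theta >= 1 - 1e-6):
        warnings.warn("estimate at boundary; clipped into [1e-6, 1-1e-6]")
    return {p: float(v) for p, v in zip(model.parameters, theta)}
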