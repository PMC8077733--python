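"""Boolean logic trees over binary heat indicators, learned by simulated annealing.

A *logic tree* is a full binary tree whose internal nodes carry AND/OR and
whose leaves are possibly-complemented binary predictors (here: lagged
extreme-heat indicators).  It defines a daily exposure rule H(X_t) in {0,1}.
Trees are learned by minimising the residual sum of squares of a least-squares
fit of a response (stage-2 Pearson residuals) on the tree output, searching
the space of trees with simulated annealing; the number of leaves is chosen
by 10-fold cross-validation.

Canonical form is the disjunctive normal form (DNF): an OR of AND-clauses of
literals, with contradictory clauses dropped, duplicates removed and
absorption applied.  Two trees are equivalent iff their truth tables agree,
which is checked exhaustively for small predictor counts.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Leaf",
    "Node",
    "LogicTree",
    "DNFForm",
    "AnnealingSchedule",
    "TreeScore",
    "evaluate_matrix",
    "to_dnf",
    "dnf_string",
    "truth_table",
    "trees_equivalent",
    "complement_tree",
    "propose_move",
    "score_tree",
    "anneal",
    "enumerate_boolean_functions",
    "exhaustive_best_tree",
    "select_tree_size",
    "orient_reference",
]


# ---------------------------------------------------------------------------
# Tree representation


@dataclass(frozen=True)
class Leaf:
    """A literal: predictor column ``index``, negated when ``complemented``."""

    index: int
    complemented: bool = False


@dataclass(frozen=True)
class Node:
    """An internal AND/OR node with exactly two children."""

    op: str  # "and" | "or"
    left: "Node | Leaf"
    right: "Node | Leaf"

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"operator must be 'and' or 'or', got {self.op!r}")


def _count_leaves(node) -> int:
    if isinstance(node, Leaf):
        return 1
    return _count_leaves(node.left) + _count_leaves(node.right)


def _max_index(node) -> int:
    if isinstance(node, Leaf):
        return node.index
    return max(_max_index(node.left), _max_index(node.right))


@dataclass(frozen=True)
class LogicTree:
    """A full binary AND/OR tree over possibly-complemented binary predictors."""

    root: Node | Leaf

    @property
    def n_leaves(self) -> int:
        return _count_leaves(self.root)

    def evaluate(self, x) -> float:
        """Evaluate on a single 0/1 assignment vector; NaN entries propagate."""
        return float(evaluate_matrix(self, np.atleast_2d(np.asarray(x, dtype=float)))[0])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def rec(node):
            if isinstance(node, Leaf):
                return {"type": "leaf", "index": node.index, "complemented": node.complemented}
            return {"type": "node", "op": node.op, "left": rec(node.left), "right": rec(node.right)}

        return rec(self.root)

    @classmethod
    def from_dict(cls, d: dict) -> "LogicTree":
        def rec(d):
            if d["type"] == "leaf":
                return Leaf(int(d["index"]), bool(d.get("complemented", False)))
            return Node(d["op"], rec(d["left"]), rec(d["right"]))

        return cls(rec(d))

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "LogicTree":
        return cls.from_dict(json.loads(s))

    def describe(self, labels: list[str] | None = None) -> str:
        return dnf_string(to_dnf(self), labels)


def evaluate_matrix(tree: LogicTree, X) -> np.ndarray:
    """Vectorised evaluation of a tree over the rows of a 0/1 matrix.

    Missing (NaN) values propagate: a row with NaN at any index the tree
    references yields NaN, to be excluded downstream.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if _max_index(tree.root) >= X.shape[1]:
        raise IndexError("tree references a predictor index beyond the matrix width")

    def rec(node):
        if isinstance(node, Leaf):
            col = X[:, node.index]
            return 1.0 - col if node.complemented else col
        a, b = rec(node.left), rec(node.right)
        if node.op == "and":
            return a * b
        return a + b - a * b

    return rec(tree.root)


# ---------------------------------------------------------------------------
# DNF and equivalence

# A literal is encoded as 2*index + complemented; a clause is a sorted tuple
# of literal codes; a DNF is a sorted tuple of clauses.


@dataclass(frozen=True)
class DNFForm:
    """Canonical disjunctive normal form: an OR of AND-clauses of literals."""

    clauses: tuple[tuple[int, ...], ...]  # each clause: sorted literal codes

    @property
    def is_false(self) -> bool:
        return len(self.clauses) == 0

    def literals(self, clause: tuple[int, ...]) -> list[tuple[int, bool]]:
        return [(code // 2, bool(code % 2)) for code in clause]


def _clause_contradictory(clause: frozenset[int]) -> bool:
    return any((code ^ 1) in clause for code in clause)


def to_dnf(tree: LogicTree) -> DNFForm:
    """Expand a tree to canonical DNF (distributive law, absorption, dedup)."""

    def rec(node) -> list[frozenset[int]]:
        if isinstance(node, Leaf):
            return [frozenset({2 * node.index + int(node.complemented)})]
        a, b = rec(node.left), rec(node.right)
        if node.op == "or":
            return a + b
        out = []
        for ca in a:
            for cb in b:
                merged = ca | cb
                if not _clause_contradictory(merged):
                    out.append(merged)
        return out

    clauses = rec(tree.root)
    # absorption: drop any clause that is a superset of another
    uniq = sorted(set(clauses), key=len)
    kept: list[frozenset[int]] = []
    for c in uniq:
        if not any(k <= c for k in kept):
            kept.append(c)
    return DNFForm(tuple(sorted(tuple(sorted(c)) for c in kept)))


_DEFAULT_LABELS = [f"lag{i}" for i in range(16)]


def dnf_string(dnf: DNFForm, labels: list[str] | None = None) -> str:
    """Human-readable rendering, e.g. ``(lag0 AND lag1) OR (lag1 AND lag3)``."""
    labels = labels or _DEFAULT_LABELS
    if dnf.is_false:
        return "FALSE"
    parts = []
    for clause in dnf.clauses:
        lits = [
            f"NOT {labels[idx]}" if comp else labels[idx]
            for idx, comp in dnf.literals(clause)
        ]
        text = " AND ".join(lits)
        if len(dnf.clauses) > 1 and len(lits) > 1:
            text = f"({text})"
        parts.append(text)
    return " OR ".join(parts)


def dnf_to_tree(dnf: DNFForm) -> LogicTree:
    """Rebuild a (right-deep) logic tree from a DNF; FALSE is not representable."""
    if dnf.is_false:
        raise ValueError("the constant-false function has no single-literal DNF tree")

    def clause_tree(clause):
        leaves = [Leaf(idx, comp) for idx, comp in
                  [(code // 2, bool(code % 2)) for code in clause]]
        node = leaves[-1]
        for lf in reversed(leaves[:-1]):
            node = Node("and", lf, node)
        return node

    subtrees = [clause_tree(c) for c in dnf.clauses]
    node = subtrees[-1]
    for st in reversed(subtrees[:-1]):
        node = Node("or", st, node)
    return LogicTree(node)


def truth_table(tree: LogicTree, k: int) -> np.ndarray:
    """Tree output on all 2^k assignments (assignment a has x_j = bit j of a)."""
    if k > 20:
        raise ValueError("truth-table enumeration limited to k <= 20 predictors")
    a = np.arange(2**k)[:, None]
    X = ((a >> np.arange(k)[None, :]) & 1).astype(float)
    return evaluate_matrix(tree, X).astype(int)


def trees_equivalent(a: LogicTree, b: LogicTree, k: int) -> bool:
    """True iff the two trees classify every one of the 2^k assignments identically."""
    return bool(np.array_equal(truth_table(a, k), truth_table(b, k)))


def complement_tree(tree: LogicTree) -> LogicTree:
    """Negate a tree, pushing NOT to the leaves by De Morgan's laws."""

    def rec(node):
        if isinstance(node, Leaf):
            return Leaf(node.index, not node.complemented)
        return Node("or" if node.op == "and" else "and", rec(node.left), rec(node.right))

    return LogicTree(rec(tree.root))


# ---------------------------------------------------------------------------
# Annealing moves


def _positions(node, path=()):
    """All (path, node) pairs in preorder; path is a tuple of 0/1 descents."""
    yield path, node
    if isinstance(node, Node):
        yield from _positions(node.left, path + (0,))
        yield from _positions(node.right, path + (1,))


def _replace(node, path, new):
    if not path:
        return new
    if path[0] == 0:
        return Node(node.op, _replace(node.left, path[1:], new), node.right)
    return Node(node.op, node.left, _replace(node.right, path[1:], new))


def _random_leaf(k: int, rng) -> Leaf:
    return Leaf(int(rng.integers(k)), bool(rng.integers(2)))


_MOVES = (
    "alternate_leaf",
    "complement_leaf",
    "alternate_operator",
    "grow_branch",
    "prune_branch",
    "split_leaf",
    "delete_leaf",
)


def propose_move(tree: LogicTree, k: int, max_leaves: int, rng) -> LogicTree:
    """One uniformly chosen applicable move from the classical seven-move set.

    alternate/complement leaf, alternate operator, grow/prune branch and
    split/delete leaf; the result respects ``max_leaves`` and remains a full
    binary tree.  The input tree is never modified.
    """
    positions = list(_positions(tree.root))
    leaves = [(p, n) for p, n in positions if isinstance(n, Leaf)]
    internals = [(p, n) for p, n in positions if isinstance(n, Node)]
    n_leaves = len(leaves)

    applicable = ["complement_leaf"]
    if k > 1:
        applicable.append("alternate_leaf")
    if internals:
        applicable += ["alternate_operator", "prune_branch", "delete_leaf"]
    if n_leaves < max_leaves:
        applicable += ["grow_branch", "split_leaf"]

    move = applicable[int(rng.integers(len(applicable)))]

    if move == "alternate_leaf":
        path, leaf = leaves[int(rng.integers(len(leaves)))]
        new_index = int(rng.integers(k - 1))
        if new_index >= leaf.index:
            new_index += 1
        return LogicTree(_replace(tree.root, path, Leaf(new_index, bool(rng.integers(2)))))

    if move == "complement_leaf":
        path, leaf = leaves[int(rng.integers(len(leaves)))]
        return LogicTree(_replace(tree.root, path, Leaf(leaf.index, not leaf.complemented)))

    if move == "alternate_operator":
        path, node = internals[int(rng.integers(len(internals)))]
        flipped = Node("or" if node.op == "and" else "and", node.left, node.right)
        return LogicTree(_replace(tree.root, path, flipped))

    if move == "grow_branch":
        path, sub = positions[int(rng.integers(len(positions)))]
        op = "and" if rng.integers(2) else "or"
        new_leaf = _random_leaf(k, rng)
        grown = Node(op, sub, new_leaf) if rng.integers(2) else Node(op, new_leaf, sub)
        return LogicTree(_replace(tree.root, path, grown))

    if move == "prune_branch":
        path, node = internals[int(rng.integers(len(internals)))]
        child = node.left if rng.integers(2) else node.right
        return LogicTree(_replace(tree.root, path, child))

    if move == "split_leaf":
        path, leaf = leaves[int(rng.integers(len(leaves)))]
        op = "and" if rng.integers(2) else "or"
        split = Node(op, leaf, _random_leaf(k, rng))
        return LogicTree(_replace(tree.root, path, split))

    # delete_leaf: remove a leaf whose parent is then replaced by its sibling
    path, leaf = leaves[int(rng.integers(len(leaves)))]
    parent_path = path[:-1]
    parent = tree.root
    for step in parent_path:
        parent = parent.left if step == 0 else parent.right
    sibling = parent.right if path[-1] == 0 else parent.left
    return LogicTree(_replace(tree.root, parent_path, sibling))


# ---------------------------------------------------------------------------
# Scoring


@dataclass(frozen=True)
class TreeScore:
    """Least-squares fit of the response on (1, H): residual sum of squares."""

    rss: float
    intercept: float
    slope: float


def score_tree(tree: LogicTree, X: np.ndarray, r: np.ndarray) -> TreeScore:
    """RSS of regressing r on the tree's 0/1 output, with intercept.

    A constant tree output leaves the slope undefined; the score is then the
    (centred) total sum of squares with zero slope.
    """
    H = evaluate_matrix(tree, X)
    return _score_output(H, r)


def _score_output(H: np.ndarray, r: np.ndarray) -> TreeScore:
    n = r.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to score a tree")
    total = float(r.sum())
    n1 = float(H.sum())
    if n1 <= 0 or n1 >= n:  # constant output
        mean = total / n
        rss = float(((r - mean) ** 2).sum())
        return TreeScore(rss=rss, intercept=mean, slope=0.0)
    s1 = float(r @ H)
    m1 = s1 / n1
    m0 = (total - s1) / (n - n1)
    rss = float((r**2).sum() - n1 * m1**2 - (n - n1) * m0**2)
    return TreeScore(rss=max(rss, 0.0), intercept=m0, slope=m1 - m0)


# ---------------------------------------------------------------------------
# Simulated annealing


@dataclass
class AnnealingSchedule:
    """Geometric cooling schedule; temperatures auto-calibrated when None.

    Auto-calibration samples random moves from random trees and sets the
    start temperature so a typical uphill move is accepted with probability
    ~0.9 and the end temperature so it is accepted with probability ~1e-3.
    """

    n_iterations: int = 25_000
    start_temperature: float | None = None
    end_temperature: float | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if (
            self.start_temperature is not None
            and self.end_temperature is not None
            and not (0 < self.end_temperature < self.start_temperature)
        ):
            raise ValueError("need 0 < end_temperature < start_temperature")


def _calibrate(X, r, k, max_leaves, rng, n_probe=200):
    """Median uphill score change over random moves, for temperature scaling."""
    deltas = []
    tree = LogicTree(_random_leaf(k, rng))
    cur = score_tree(tree, X, r).rss
    for _ in range(n_probe):
        nxt = propose_move(tree, k, max_leaves, rng)
        s = score_tree(nxt, X, r).rss
        d = s - cur
        if d > 0:
            deltas.append(d)
        tree, cur = nxt, s
    if not deltas:
        return 1.0
    return float(np.median(deltas))


def _canonical_key(tree: LogicTree):
    return to_dnf(tree).clauses


def anneal(
    X: np.ndarray,
    r: np.ndarray,
    max_leaves: int,
    schedule: AnnealingSchedule | None = None,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = 0,
) -> LogicTree:
    """Learn the RSS-minimising logic tree by simulated annealing.

    Metropolis acceptance min{1, exp(-(score_new - score_cur)/temperature)}
    under geometric cooling; the best tree ever visited across ``n_restarts``
    independent chains is returned.  Deterministic given the seed; score ties
    are broken toward the lexicographically smallest canonical DNF.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    if X.shape[0] != r.shape[0]:
        raise ValueError("X and r must have the same number of rows")
    if np.isnan(X).any() or np.isnan(r).any():
        raise ValueError("X and r must be complete; drop missing rows first")
    k = X.shape[1]
    schedule = schedule or AnnealingSchedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t0, t1 = schedule.start_temperature, schedule.end_temperature
    if t0 is None or t1 is None:
        scale = _calibrate(X, r, k, max_leaves, rng)
        if t0 is None:
            t0 = scale / math.log(1 / 0.9)
        if t1 is None:
            t1 = scale / math.log(1 / 1e-3)
        t1 = min(t1, t0 * 0.5)

    best_tree = None
    best_rss = math.inf
    best_key = None
    n_it = schedule.n_iterations
    ratio = t1 / t0
    for _ in range(max(1, n_restarts)):
        tree = LogicTree(_random_leaf(k, rng))
        cur = score_tree(tree, X, r).rss
        for i in range(n_it):
            temp = t0 * ratio ** (i / max(n_it - 1, 1))
            prop = propose_move(tree, k, max_leaves, rng)
            s = score_tree(prop, X, r).rss
            d = s - cur
            if d <= 0 or rng.random() < math.exp(-d / temp):
                tree, cur = prop, s
                if cur < best_rss - 1e-12:
                    best_tree, best_rss, best_key = tree, cur, None
                elif abs(cur - best_rss) <= 1e-12:
                    if best_key is None:
                        best_key = _canonical_key(best_tree)
                    key = _canonical_key(tree)
                    if key < best_key:
                        best_tree, best_key = tree, key
    return best_tree


# ---------------------------------------------------------------------------
# Exhaustive enumeration (test oracle and small-instance solver)


def enumerate_boolean_functions(k: int, max_leaves: int | None = None):
    """All Boolean functions of k inputs representable with <= max_leaves leaves.

    Returns ``{signature: tree}`` where the signature is the truth table
    packed into an int (bit a = output on assignment a).  With
    ``max_leaves=None`` iterates to closure — all 2^(2^k) functions for
    small k, since x AND NOT x / x OR NOT x supply the constants.
    """
    if k > 4 or (max_leaves is None and k > 3):
        raise ValueError("exhaustive enumeration supported only for small k")
    n_assign = 2**k
    a = np.arange(n_assign)

    def sig_of_bits(bits) -> int:
        return int(np.sum((bits.astype(np.int64)) << a))

    lit_sigs = {}
    for idx in range(k):
        bits = (a >> idx) & 1
        lit_sigs[sig_of_bits(bits)] = LogicTree(Leaf(idx, False))
        lit_sigs[sig_of_bits(1 - bits)] = LogicTree(Leaf(idx, True))

    by_size: list[dict[int, LogicTree]] = [dict(), dict(lit_sigs)]
    found: dict[int, LogicTree] = dict(lit_sigs)

    # any k-input function has a DNF with <= k * 2^(k-1) literals
    size_cap = max_leaves if max_leaves is not None else k * 2 ** (k - 1)
    for size in range(2, size_cap + 1):
        new: dict[int, LogicTree] = {}
        for i in range(1, size):
            j = size - i
            for sa, ta in by_size[i].items():
                for sb, tb in by_size[j].items():
                    for op, sig in (("and", sa & sb), ("or", sa | sb)):
                        if sig not in found and sig not in new:
                            new[sig] = LogicTree(Node(op, ta.root, tb.root))
        by_size.append(new)
        found.update(new)
        if len(found) == (1 << n_assign):
            break
    return found


def exhaustive_best_tree(
    X: np.ndarray, r: np.ndarray, max_leaves: int = 3, k: int | None = None
) -> LogicTree:
    """RSS-minimising tree by complete enumeration; small instances only.

    Ties are broken toward the lexicographically smallest canonical DNF.
    Serves as the independent optimum against which annealing is audited.
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    k = k if k is not None else X.shape[1]
    if k > 4 or max_leaves > 3:
        raise ValueError("exhaustive search supports k <= 4 and max_leaves <= 3 only")
    funcs = enumerate_boolean_functions(k, max_leaves)
    # group rows by assignment so each function is scored via a k-bit lookup
    codes = (X[:, :k].astype(np.int64) * (1 << np.arange(k))).sum(axis=1)
    best = None
    for sig, tree in funcs.items():
        H = ((sig >> codes) & 1).astype(float)
        s = _score_output(H, r).rss
        key = (s, to_dnf(tree).clauses)
        if best is None or key < best[0]:
            best = (key, tree)
    return best[1]


# ---------------------------------------------------------------------------
# Cross-validated size selection and reference orientation


def select_tree_size(
    X: np.ndarray,
    r: np.ndarray,
    candidate_sizes=(0, 1, 2, 3),
    n_folds: int = 10,
    seed: int | np.random.Generator | None = 0,
    schedule: AnnealingSchedule | None = None,
    n_restarts: int = 2,
    blocked: bool = False,
) -> int:
    """Choose the number of leaves by K-fold cross-validation.

    For each candidate size an annealing run on each training fold is scored
    by held-out RSS of the fitted two-group means; size 0 denotes the null
    (intercept-only) model.  The size with the smallest mean CV error wins;
    ties go to the smaller size.  Folds are random rows by default;
    ``blocked=True`` uses contiguous blocks instead (conservative under
    temporal autocorrelation).
    """
    X = np.asarray(X, dtype=float)
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if not candidate_sizes:
        raise ValueError("candidate_sizes must be non-empty")
    if n < n_folds * 2:
        raise ValueError(f"too few rows ({n}) for {n_folds}-fold cross-validation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = np.arange(n) if blocked else rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    cv_err = {}
    for size in sorted(candidate_sizes):
        err = 0.0
        for f in folds:
            test = np.zeros(n, dtype=bool)
            test[f] = True
            Xtr, rtr = X[~test], r[~test]
            Xte, rte = X[test], r[test]
            if size == 0:
                pred = np.full(len(rte), rtr.mean())
            else:
                tree = anneal(Xtr, rtr, max_leaves=size, schedule=schedule,
                              n_restarts=n_restarts, seed=rng)
                sc = score_tree(tree, Xtr, rtr)
                Hte = evaluate_matrix(tree, Xte)
                pred = sc.intercept + sc.slope * Hte
            err += float(((rte - pred) ** 2).sum())
        cv_err[size] = err
    best = min(cv_err, key=lambda s: (cv_err[s], s))
    return best


def orient_reference(tree: LogicTree, X: np.ndarray) -> LogicTree:
    """Ensure exposed days (H=1) are the minority; complement the tree otherwise.

    The reference group H=0 is defined as the more frequently observed type
    of day; an exact 50/50 split returns the tree unchanged with a warning.
    """
    H = evaluate_matrix(tree, np.asarray(X, dtype=float))
    H = H[~np.isnan(H)]
    frac = H.mean() if len(H) else 0.0
    if frac > 0.5:
        return complement_tree(tree)
    if frac == 0.5:
        warnings.warn("exposure splits days exactly 50/50; reference orientation ambiguous",
                      stacklevel=2)
    return tree
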