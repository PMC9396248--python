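"""Threshold decision trees for subtype annotation, the gene-ratio
classifier, and pairwise-enrichment gene-signature derivation.

Rule sets are data: an ordered list of (label, boolean expression) steps
over per-cell features (module detection scores m1..mk, topic weights
t1..tK, cluster id, gene ratios) plus a fallback label.  Steps are
evaluated in order and the first true expression wins, so cluster
pre-assignments placed before score rules take precedence.  All
thresholds are strict inequalities: boundary values fall through.
"""

from __future__ import annotations

import ast
import operator
from dataclasses import dataclass, field
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "RuleSet",
    "SignatureSpec",
    "classify_cells",
    "ratio_classify",
    "derive_signature",
]

_BIN_OPS = {ast.Add: operator.add, ast.Sub: operator.sub, ast.Mult: operator.mul, ast.Div: operator.truediv}
_CMP_OPS = {
    ast.Gt: operator.gt,
    ast.GtE: operator.ge,
    ast.Lt: operator.lt,
    ast.LtE: operator.le,
    ast.Eq: operator.eq,
    ast.NotEq: operator.ne,
}


def _compile(expr: str):
    """Compile a restricted boolean expression to a vectorized closure.

    Supported grammar: and/or/not, comparisons (incl. chained and ``in``
    over a literal tuple/list), +,-,*,/, feature names, numeric literals.
    """
    tree = ast.parse(expr, mode="eval").body

    def build(node):
        if isinstance(node, ast.BoolOp):
            parts = [build(v) for v in node.values]
            op = np.logical_and if isinstance(node.op, ast.And) else np.logical_or
            return lambda env: _reduce(op, [p(env) for p in parts])
        if isinstance(node, ast.UnaryOp):
            inner = build(node.operand)
            if isinstance(node.op, ast.Not):
                return lambda env: np.logical_not(inner(env))
            if isinstance(node.op, ast.USub):
                return lambda env: -inner(env)
            raise ValueError(f"unsupported unary operator in {expr!r}")
        if isinstance(node, ast.Compare):
            left = build(node.left)
            out = []
            for op, comp in zip(node.ops, node.comparators):
                if isinstance(op, ast.In):
                    if not isinstance(comp, (ast.Tuple, ast.List)):
                        raise ValueError(f"'in' requires a literal tuple in {expr!r}")
                    vals = [ast.literal_eval(e) for e in comp.elts]
                    lf = left
                    out.append(lambda env, lf=lf, vals=vals: np.isin(lf(env), vals))
                elif type(op) in _CMP_OPS:
                    rf = build(comp)
                    lf = left
                    fn = _CMP_OPS[type(op)]
                    out.append(lambda env, lf=lf, rf=rf, fn=fn: fn(lf(env), rf(env)))
                else:
                    raise ValueError(f"unsupported comparator in {expr!r}")
                left = build(comp) if not isinstance(op, ast.In) else left
            return lambda env: _reduce(np.logical_and, [o(env) for o in out])
        if isinstance(node, ast.BinOp) and type(node.op) in _BIN_OPS:
            lf, rf, fn = build(node.left), build(node.right), _BIN_OPS[type(node.op)]
            return lambda env: fn(lf(env), rf(env))
        if isinstance(node, ast.Name):
            name = node.id
            def lookup(env, name=name):
                if name not in env:
                    raise KeyError(f"feature {name!r} missing from the feature table")
                return env[name]
            return lookup
        if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            return lambda env: node.value
        raise ValueError(f"unsupported syntax in rule expression {expr!r}")

    return build(tree)


def _reduce(op, parts):
    out = parts[0]
    for p in parts[1:]:
        out = op(out, p)
    return out


def _names_in(expr: str) -> set[str]:
    return {n.id for n in ast.walk(ast.parse(expr, mode="eval")) if isinstance(n, ast.Name)}


@dataclass
class RuleSet:
    """Ordered decision list: first step whose expression is true labels
    the cell; otherwise the fallback label applies."""

    name: str
    steps: list[tuple[str, str]]  # (label, expression)
    fallback: str
    _compiled: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._compiled = [(_label, _compile(expr)) for _label, expr in self.steps]

    @property
    def features(self) -> set[str]:
        out: set[str] = set()
        for _, expr in self.steps:
            out |= _names_in(expr)
        return out

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            name=doc["name"],
            steps=[(s["label"], s["when"]) for s in doc["steps"]],
            fallback=doc["fallback"],
        )

    @classmethod
    def builtin(cls, name: str) -> "RuleSet":
        """Load one of the shipped rule sets: cd4, gd_cd8, ilc, b."""
        ref = resources.files("ileumatlas") / "rulesets" / f"{name}.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


def classify_cells(features: pd.DataFrame, rules: RuleSet) -> pd.Series:
    """Apply a RuleSet to a per-cell feature table; returns one label per
    cell (every cell gets exactly one)."""
    missing = rules.features - set(features.columns)
    if missing:
        raise KeyError(f"features missing from table: {sorted(missing)}")
    env = {c: features[c].to_numpy() for c in features.columns}
    n = len(features)
    labels = np.array([rules.fallback] * n, dtype=object)
    assigned = np.zeros(n, dtype=bool)
    for label, fn in rules._compiled:
        hit = np.asarray(fn(env), dtype=bool) & ~assigned
        labels[hit] = label
        assigned |= hit
    return pd.Series(labels, index=features.index, name=rules.name)


def ratio_classify(
    norm: ad.AnnData,
    gene_a: str,
    gene_b: str,
    labels: tuple[str, str] = ("gd T", "CD8 ab T"),
) -> pd.Series:
    """Classify each cell by the ratio of two log-normalized genes.

    ratio > 1 assigns the first label, otherwise the second; 0/0 goes to
    the second label and x/0 with x > 0 to the first.
    """
    for g in (gene_a, gene_b):
        if g not in norm.var_names:
            raise KeyError(f"gene {g!r} not found")
    a_label, b_label = labels
    x = norm[:, [gene_a, gene_b]].X
    x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)
    a, b = x[:, 0], x[:, 1]
    out = np.where(b > 0, np.where(a > b, a_label, b_label), np.where(a > 0, a_label, b_label))
    return pd.Series(out, index=norm.obs_names, name=f"{gene_a}/{gene_b}")


@dataclass
class SignatureSpec:
    """Pairwise-enrichment filter for deriving a gene signature from a
    module's candidate genes."""

    candidate_genes: list[str]
    target_subsets: list[str]
    nontarget_subsets: list[str]
    pct_floor: float = 0.10
    fold_pct: float = 2.0
    fold_expr: float = 2.0
    expressers_only_mean: bool = False

    def __post_init__(self) -> None:
        if not self.target_subsets or not self.nontarget_subsets:
            raise ValueError("target and nontarget subset lists must be non-empty")
        if set(self.target_subsets) & set(self.nontarget_subsets):
            raise ValueError("target and nontarget subsets must be disjoint")


def derive_signature(
    norm: ad.AnnData, labels: pd.Series | np.ndarray, spec: SignatureSpec
) -> tuple[list[str], pd.DataFrame]:
    """Filter candidate genes into a signature for the target subsets.

    A gene is kept iff it is detected in > pct_floor of cells in EVERY
    target subset, and for every (target, nontarget) pair either
    (1) pct_t >= fold_pct * pct_n, or
    (2) pct_n < pct_t < fold_pct * pct_n and mean_t >= fold_expr * mean_n,
    where pct is the detection fraction and mean is the average
    log-normalized count over all cells of the subset (over expressing
    cells only when ``spec.expressers_only_mean`` is set).  Returns (signature gene list,
    per-(gene, pair) evidence table recording the satisfied branch).
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=norm.obs_names)
    subsets = spec.target_subsets + spec.nontarget_subsets
    masks = {}
    for s in subsets:
        m = (labels == s).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"subset {s!r} has no cells")
        masks[s] = m
    present = [g for g in spec.candidate_genes if g in norm.var_names]
    sub = norm[:, present]
    x = sub.X
    dense = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)

    pct = {s: (dense[m] > 0).mean(axis=0) for s, m in masks.items()}
    if spec.expressers_only_mean:
        mean = {}
        for s, m in masks.items():
            block = dense[m]
            nnz = (block > 0).sum(axis=0)
            mean[s] = np.where(nnz > 0, block.sum(axis=0) / np.maximum(nnz, 1), 0.0)
    else:
        mean = {s: dense[m].mean(axis=0) for s, m in masks.items()}

    kept, rows = [], []
    for j, g in enumerate(present):
        floor_ok = all(pct[t][j] > spec.pct_floor for t in spec.target_subsets)
        gene_ok = floor_ok
        for t in spec.target_subsets:
            for nt in spec.nontarget_subsets:
                pt, pn = pct[t][j], pct[nt][j]
                mt, mn = mean[t][j], mean[nt][j]
                branch1 = pt >= spec.fold_pct * pn
                branch2 = (pn < pt < spec.fold_pct * pn) and (mt >= spec.fold_expr * mn)
                rows.append(
                    {
                        "gene": g,
                        "target": t,
                        "nontarget": nt,
                        "pct_target": pt,
                        "pct_nontarget": pn,
                        "mean_target": mt,
                        "mean_nontarget": mn,
                        "branch": 1 if branch1 else (2 if branch2 else 0),
                    }
                )
                if not (branch1 or branch2):
                    gene_ok = False
        if gene_ok:
            kept.append(g)
    evidence = pd.DataFrame(rows)
    if not evidence.empty:
        evidence["pct_floor_ok"] = evidence["gene"].map(
            {g: all(pct[t][j] > spec.pct_floor for t in spec.target_subsets) for j, g in enumerate(present)}
        )
        evidence["in_signature"] = evidence["gene"].isin(kept)
    return kept, evidence
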