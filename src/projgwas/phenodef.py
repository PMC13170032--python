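"""Phenotype definitions as expression trees, and their linearization.

A definition combines feature phenotypes with boolean operators (AND, OR,
NOT), comparisons against constants (>, >=, <, <=) and elementwise
arithmetic (+, -, *).  Definitions evaluate on a phenotype matrix to a
per-sample vector; a definition like ``E119 AND NOT I10`` is a case/control
phenotype built from diagnosis-code indicators.

Boolean semantics are fuzzy so that definitions remain evaluable on
microaggregated (fractional) indicator data: ``NOT a = 1 - a``,
``a AND b = min(a, b)``, ``a OR b = max(a, b)``.  These preserve [0, 1] and
reduce to classical logic on crisp 0/1 inputs.  Product semantics
(``a*b`` / ``a + b - a*b``) are available as an option; the two coincide on
crisp data.

Because the indirect machinery needs a *linear* phenotype, a nonlinear
definition is approximated by ordinary least squares against all features:
p_hat = argmin ||y - (intercept + X p)||^2.  The coefficient of
determination R^2 between y and its approximation — the "phenotype fit
quality" — is the user-facing gauge of how trustworthy downstream indirect
statistics are.

Serialized forms: a JSON tree (canonical) and a compact prefix notation,
e.g. ``and E119 (not I10)`` or ``gt BMI 30``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LinearApproximation

logger = logging.getLogger(__name__)


class PhenotypeDefinition:
    """Base class for definition-tree nodes."""

    def to_dict(self) -> dict:
        raise NotImplementedError

    def to_prefix(self) -> str:
        raise NotImplementedError

    def feature_ids(self) -> set[str]:
        """All feature identifiers referenced in the tree."""
        out: set[str] = set()
        _collect_features(self, out)
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, PhenotypeDefinition) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.to_prefix()!r})"


@dataclass(repr=False, eq=False)
class FeatureRef(PhenotypeDefinition):
    feature_id: str

    def to_dict(self):
        return {"feature": self.feature_id}

    def to_prefix(self):
        return self.feature_id


@dataclass(repr=False, eq=False)
class Constant(PhenotypeDefinition):
    value: float

    def to_dict(self):
        return {"const": self.value}

    def to_prefix(self):
        return repr(self.value)


@dataclass(repr=False, eq=False)
class Not(PhenotypeDefinition):
    child: PhenotypeDefinition

    def to_dict(self):
        return {"op": "not", "args": [self.child.to_dict()]}

    def to_prefix(self):
        return f"not ({self.child.to_prefix()})"


@dataclass(repr=False, eq=False)
class _Binary(PhenotypeDefinition):
    left: PhenotypeDefinition
    right: PhenotypeDefinition
    op: str = ""

    def to_dict(self):
        return {"op": self.op, "args": [self.left.to_dict(), self.right.to_dict()]}

    def to_prefix(self):
        return f"{self.op} ({self.left.to_prefix()}) ({self.right.to_prefix()})"


class And(_Binary):
    def __init__(self, left, right):
        super().__init__(left, right, "and")


class Or(_Binary):
    def __init__(self, left, right):
        super().__init__(left, right, "or")


class Add(_Binary):
    def __init__(self, left, right):
        super().__init__(left, right, "add")


class Sub(_Binary):
    def __init__(self, left, right):
        super().__init__(left, right, "sub")


class Mul(_Binary):
    def __init__(self, left, right):
        super().__init__(left, right, "mul")


@dataclass(repr=False, eq=False)
class Comparison(PhenotypeDefinition):
    """child <op> threshold, yielding 0/1 per sample."""

    child: PhenotypeDefinition
    threshold: float
    op: str = "gt"  # gt | ge | lt | le

    def to_dict(self):
        return {"op": self.op, "args": [self.child.to_dict()], "threshold": self.threshold}

    def to_prefix(self):
        return f"{self.op} ({self.child.to_prefix()}) {self.threshold!r}"


def Gt(child, threshold):
    return Comparison(child, threshold, "gt")


def Ge(child, threshold):
    return Comparison(child, threshold, "ge")


def Lt(child, threshold):
    return Comparison(child, threshold, "lt")


def Le(child, threshold):
    return Comparison(child, threshold, "le")


def _collect_features(node: PhenotypeDefinition, out: set[str]) -> None:
    if isinstance(node, FeatureRef):
        out.add(node.feature_id)
    elif isinstance(node, Not):
        _collect_features(node.child, out)
    elif isinstance(node, Comparison):
        _collect_features(node.child, out)
    elif isinstance(node, _Binary):
        _collect_features(node.left, out)
        _collect_features(node.right, out)


# ---------------------------------------------------------------------------
# parsing / serialization

_BINARY_OPS = {"and": And, "or": Or, "add": Add, "sub": Sub, "mul": Mul}
_CMP_OPS = {"gt", "ge", "lt", "le"}
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class DefinitionSyntaxError(ValueError):
    """Malformed definition text, with the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token {position})")
        self.position = position


def _tokenize(text: str) -> list[str]:
    return re.findall(r"\(|\)|[^\s()]+", text)


def _from_tokens(tokens: list[str], pos: int) -> tuple[PhenotypeDefinition, int]:
    if pos >= len(tokens):
        raise DefinitionSyntaxError("unexpected end of definition", pos)
    tok = tokens[pos]
    if tok == "(":
        node, pos = _from_tokens(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise DefinitionSyntaxError("expected ')'", pos)
        return node, pos + 1
    if tok == ")":
        raise DefinitionSyntaxError("unexpected ')'", pos)
    if tok == "not":
        child, pos = _from_tokens(tokens, pos + 1)
        return Not(child), pos
    if tok in _BINARY_OPS:
        left, pos = _from_tokens(tokens, pos + 1)
        right, pos = _from_tokens(tokens, pos)
        return _BINARY_OPS[tok](left, right), pos
    if tok in _CMP_OPS:
        child, pos = _from_tokens(tokens, pos + 1)
        if pos >= len(tokens) or not _NUMBER_RE.match(tokens[pos]):
            raise DefinitionSyntaxError("comparison needs a numeric threshold", pos)
        return Comparison(child, float(tokens[pos]), tok), pos + 1
    if _NUMBER_RE.match(tok):
        return Constant(float(tok)), pos + 1
    return FeatureRef(tok), pos + 1


def _from_dict(d: dict) -> PhenotypeDefinition:
    if "feature" in d:
        return FeatureRef(d["feature"])
    if "const" in d:
        return Constant(float(d["const"]))
    op = d.get("op")
    args = [_from_dict(a) for a in d.get("args", [])]
    if op == "not":
        (child,) = args
        return Not(child)
    if op in _CMP_OPS:
        (child,) = args
        return Comparison(child, float(d["threshold"]), op)
    if op in _BINARY_OPS:
        left, right = args
        return _BINARY_OPS[op](left, right)
    raise ValueError(f"unknown definition node: {d!r}")


def parse_definition(text: str, feature_catalog=None) -> PhenotypeDefinition:
    """Parse a JSON tree or prefix-notation definition string.

    If ``feature_catalog`` is given, every referenced feature must resolve
    against it.  Round-trips: ``parse_definition(d.to_prefix()) == d`` and
    ``parse_definition(json.dumps(d.to_dict())) == d``.
    """
    text = text.strip()
    if text.startswith("{"):
        node = _from_dict(json.loads(text))
    else:
        tokens = _tokenize(text)
        node, pos = _from_tokens(tokens, 0)
        if pos != len(tokens):
            raise DefinitionSyntaxError("trailing tokens after definition", pos)
    if feature_catalog is not None:
        unknown = node.feature_ids() - set(feature_catalog)
        if unknown:
            raise ValueError(f"unknown feature id(s): {sorted(unknown)}")
    return node


def serialize_definition(d: PhenotypeDefinition, form: str = "prefix") -> str:
    if form == "prefix":
        return d.to_prefix()
    if form == "json":
        return json.dumps(d.to_dict())
    raise ValueError(f"unknown serialization form {form!r}")


# ---------------------------------------------------------------------------
# evaluation

def _check_unit_interval(a: np.ndarray, node: PhenotypeDefinition) -> None:
    if np.nanmin(a) < -1e-9 or np.nanmax(a) > 1 + 1e-9:
        raise ValueError(
            f"boolean node {type(node).__name__} received values outside [0, 1]"
        )


def evaluate_definition(
    d: PhenotypeDefinition, X: pd.DataFrame, bool_mode: str = "minmax"
) -> pd.Series:
    """Evaluate a definition on a phenotype matrix, one value per sample.

    ``bool_mode`` selects the fuzzy-logic family used on fractional inputs:
    ``"minmax"`` (default; AND=min, OR=max) or ``"product"`` (AND=a*b,
    OR=a+b-ab).  Both reduce to classical logic on {0,1} data.  Boolean
    nodes reject inputs outside [0, 1].
    """
    if bool_mode not in ("minmax", "product"):
        raise ValueError(f"unknown bool_mode {bool_mode!r}")

    def ev(node: PhenotypeDefinition) -> np.ndarray:
        if isinstance(node, FeatureRef):
            if node.feature_id not in X.columns:
                raise KeyError(f"feature {node.feature_id!r} not in phenotype matrix")
            return X[node.feature_id].to_numpy(dtype=float)
        if isinstance(node, Constant):
            return np.full(len(X), node.value)
        if isinstance(node, Not):
            a = ev(node.child)
            _check_unit_interval(a, node)
            return 1.0 - a
        if isinstance(node, Comparison):
            a = ev(node.child)
            cmp = {
                "gt": np.greater, "ge": np.greater_equal,
                "lt": np.less, "le": np.less_equal,
            }[node.op]
            return cmp(a, node.threshold).astype(float)
        if isinstance(node, (And, Or)):
            a, b = ev(node.left), ev(node.right)
            _check_unit_interval(a, node)
            _check_unit_interval(b, node)
            if isinstance(node, And):
                return np.minimum(a, b) if bool_mode == "minmax" else a * b
            return np.maximum(a, b) if bool_mode == "minmax" else a + b - a * b
        if isinstance(node, _Binary):  # arithmetic
            a, b = ev(node.left), ev(node.right)
            return {"add": a + b, "sub": a - b, "mul": a * b}[node.op]
        raise TypeError(f"unknown node type {type(node).__name__}")

    return pd.Series(ev(d), index=X.index)


# ---------------------------------------------------------------------------
# linearization

def fit_quality(y: pd.Series | np.ndarray, y_hat: pd.Series | np.ndarray) -> float:
    """Coefficient of determination R^2 = 1 - RSS/TSS between a target
    phenotype and its approximation.  Constant targets (zero TSS) are
    flagged NaN."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must be equal-length vectors of size >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        logger.warning("constant target phenotype; fit quality flagged NA")
        return float("nan")
    rss = float(np.sum((y - y_hat) ** 2))
    return 1.0 - rss / tss


def linearize(y: pd.Series, X: pd.DataFrame) -> LinearApproximation:
    """Best linear approximation of a (possibly nonlinear) phenotype by the
    feature matrix: OLS of y on [1 | X].

    The intercept is fitted but kept out of the projection coefficients —
    association statistics are invariant to location shifts once the
    covariates include an intercept.  Rank-deficient feature matrices give
    the minimum-norm solution with a warning.  ``fit_r2`` is computed on the
    fitting data and clipped at 0.
    """
    if not y.index.equals(X.index):
        raise ValueError("sample ids of y and X do not match")
    if X.shape[1] >= X.shape[0]:
        raise ValueError("need more samples than features for the linear fit")
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    coef, _, rank, _ = np.linalg.lstsq(design, y.to_numpy(dtype=float), rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient feature matrix (rank %d of %d); minimum-norm solution",
            rank, design.shape[1],
        )
    y_hat = design @ coef
    r2 = fit_quality(y, y_hat)
    if np.isfinite(r2):
        r2 = max(0.0, r2)
    return LinearApproximation(
        coefficients=pd.Series(coef[1:], index=X.columns),
        intercept=float(coef[0]),
        fit_r2=r2,
    )
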