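"""A small text language for (in)equality-constrained hypotheses.

A hypothesis is a list of restrictions over named parameters, e.g.::

    eta1 > {eta2, eta3, eta4}        fan-out: eta1 exceeds each of the others
    eta1 = eta2, eta3 > eta4         two restrictions (comma or ; separated)
    eta1 > eta2 > eta3 > eta4        chain, expanded pairwise
    eta1 - eta2 > 0.8                constants allowed on either side
    eta1, eta2, eta3, eta4           no relations: the unconstrained hypothesis

Parsed hypotheses are stored in the linear form ``S eta = s, R eta > r``.
Strict inequalities are represented as closed constraints for optimization
(the boundary has probability zero under the sampling distributions), which
is standard order-restricted-inference practice.  Constraint rows are
normalized to a lexicographic order so that penalties and tests do not depend
on the order restrictions were written in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "LinearHypothesis",
    "HypothesisSet",
    "parse",
    "parse_set",
    "render",
    "relocate",
    "unconstrained",
    "load_packaged_set",
]


class ParseError(ValueError):
    pass


@dataclass
class LinearHypothesis:
    """Constraint system ``S eta = s, R eta > r`` over named parameters."""

    label: str
    eta_names: list[str]
    S: np.ndarray
    s: np.ndarray
    R: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.eta_names)
        self.S = np.asarray(self.S, dtype=float).reshape(-1, k)
        self.R = np.asarray(self.R, dtype=float).reshape(-1, k)
        self.s = np.asarray(self.s, dtype=float).reshape(-1)
        self.r = np.asarray(self.r, dtype=float).reshape(-1)
        if self.S.shape[0] != self.s.size or self.R.shape[0] != self.r.size:
            raise ValueError("constraint matrix/constant sizes disagree")
        for m in (self.S, self.R):
            if m.shape[0] and (np.abs(m).sum(axis=1) == 0).any():
                raise ValueError("all-zero constraint row")

    @property
    def k(self) -> int:
        return len(self.eta_names)

    @property
    def n_eq(self) -> int:
        return self.S.shape[0]

    @property
    def n_ineq(self) -> int:
        return self.R.shape[0]

    @property
    def is_unconstrained(self) -> bool:
        return self.n_eq == 0 and self.n_ineq == 0

    @property
    def equality_only(self) -> bool:
        return self.n_ineq == 0 and self.n_eq > 0

    def satisfied_by(self, eta: np.ndarray, tol: float = 1e-8) -> bool:
        eta = np.asarray(eta, dtype=float)
        ok_eq = self.n_eq == 0 or np.all(np.abs(self.S @ eta - self.s) <= tol)
        ok_in = self.n_ineq == 0 or np.all(self.R @ eta - self.r >= -tol)
        return bool(ok_eq and ok_in)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LinearHypothesis)
            and self.eta_names == other.eta_names
            and self.S.shape == other.S.shape
            and self.R.shape == other.R.shape
            and np.array_equal(self.S, other.S)
            and np.array_equal(self.s, other.s)
            and np.array_equal(self.R, other.R)
            and np.array_equal(self.r, other.r)
        )


@dataclass
class HypothesisSet:
    """An ordered set of competing hypotheses over one shared eta vector."""

    hypotheses: list[LinearHypothesis]
    include_unconstrained: bool = True

    def __post_init__(self) -> None:
        if not self.hypotheses:
            raise ValueError("empty hypothesis set")
        names = self.hypotheses[0].eta_names
        for h in self.hypotheses:
            if h.eta_names != names:
                raise ValueError("all hypotheses must share the same eta names")
        labels = [h.label for h in self.hypotheses]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate hypothesis labels in {labels}")

    @property
    def eta_names(self) -> list[str]:
        return self.hypotheses[0].eta_names

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.hypotheses]

    def with_failsafe(self) -> "HypothesisSet":
        """Append the unconstrained failsafe if requested and not present."""
        hyps = list(self.hypotheses)
        if self.include_unconstrained and not any(
            h.is_unconstrained for h in hyps
        ):
            hyps.append(unconstrained(self.eta_names))
        return HypothesisSet(hyps, include_unconstrained=False)


def unconstrained(eta_names, label: str = "Hu") -> LinearHypothesis:
    k = len(eta_names)
    return LinearHypothesis(label, list(eta_names),
                            np.zeros((0, k)), np.zeros(0),
                            np.zeros((0, k)), np.zeros(0))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TOKEN = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<num>\d+\.\d*|\.\d+|\d+)"
    r"|(?P<op>[-+*=<>{},;])"
    r"|(?P<bad>\S))"
)


def _tokenize(text: str):
    for m in _TOKEN.finditer(text):
        if m.lastgroup == "bad":
            raise ParseError(f"unexpected character {m.group()!r} at "
                             f"position {m.start()}")
        yield m.lastgroup, m.group(m.lastgroup), m.start()


def _split_top(text: str, seps=",;\n") -> list[str]:
    """Split on separators at brace depth zero."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
            if depth < 0:
                raise ParseError("unbalanced '}'")
        if ch in seps and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise ParseError("unbalanced '{'")
    parts.append("".join(cur))
    return [p.strip() for p in parts if p.strip()]


def _strip_outer_braces(expr: str) -> str:
    expr = expr.strip()
    while expr.startswith("{") and expr.endswith("}"):
        depth = 0
        for i, ch in enumerate(expr):
            depth += ch == "{"
            depth -= ch == "}"
            if depth == 0 and i < len(expr) - 1:
                return expr
        expr = expr[1:-1].strip()
    return expr


def _parse_linear(expr: str, name_to_idx: dict[str, int]) -> tuple[np.ndarray, float]:
    """Parse a linear combination into (coefficients, constant)."""
    coefs = np.zeros(len(name_to_idx))
    const = 0.0
    sign = 1.0
    pending: float | None = None  # numeric factor awaiting '*name' or flush
    expect_operand = True
    last_was_name = False

    def flush_pending():
        nonlocal const, pending
        if pending is not None:
            const += sign * pending
            pending = None

    for kind, tok, pos in _tokenize(expr):
        if kind == "op" and tok in "+-":
            if expect_operand and tok == "-":
                sign = -sign
                continue
            if expect_operand:
                continue
            flush_pending()
            sign = 1.0 if tok == "+" else -1.0
            expect_operand, last_was_name = True, False
        elif kind == "op" and tok == "*":
            if pending is None and not last_was_name:
                raise ParseError(f"misplaced '*' at position {pos} in {expr!r}")
            expect_operand, last_was_name = True, last_was_name
        elif kind == "num":
            if not expect_operand:
                raise ParseError(f"unexpected number at position {pos} in {expr!r}")
            if last_was_name:
                raise ParseError(
                    f"number after name needs an operator at {pos} in {expr!r}")
            pending = float(tok)
            expect_operand, last_was_name = False, False
        elif kind == "name":
            if tok not in name_to_idx:
                raise ParseError(
                    f"unknown parameter {tok!r} at position {pos} in {expr!r}")
            if last_was_name:
                raise ParseError(
                    f"product of two parameters (non-linear term) at "
                    f"position {pos} in {expr!r}")
            factor = pending if pending is not None else 1.0
            pending = None
            coefs[name_to_idx[tok]] += sign * factor
            expect_operand, last_was_name = False, True
        else:
            raise ParseError(f"unexpected token {tok!r} at position {pos} "
                             f"in {expr!r}")
    if expect_operand and (coefs != 0).sum() == 0 and pending is None and const == 0:
        raise ParseError(f"empty expression in {expr!r}")
    flush_pending()
    return coefs, const


def _split_relations(expr: str) -> tuple[list[str], list[str]]:
    """Split an expression on top-level relations into sides and operators."""
    sides, ops, depth, cur = [], [], 0, []
    for ch in expr:
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
        if depth == 0 and ch in "=<>":
            sides.append("".join(cur))
            ops.append(ch)
            cur = []
        else:
            cur.append(ch)
    sides.append("".join(cur))
    return [s.strip() for s in sides], ops


def _members(side: str) -> list[str]:
    """A side is either a brace set {a, b, ...} or a single linear term."""
    side = side.strip()
    if side.startswith("{") and side.endswith("}"):
        inner = side[1:-1]
        return _split_top(inner)
    return [side]


def parse(text: str, eta_names, label: str = "H") -> LinearHypothesis:
    """Parse constraint expressions into a :class:`LinearHypothesis`.

    Expressions are separated by ``;``, ``,`` or newlines (at brace depth
    zero).  Within an expression, chains expand pairwise and a brace set on
    either side of a relation fans out into one row per member.  ``<`` rows
    are negated into ``>`` rows; constants move to the right-hand side with
    the convention ``R eta > r``, ``S eta = s``.
    """
    eta_names = list(eta_names)
    name_to_idx = {n: i for i, n in enumerate(eta_names)}
    S_rows, s_vals, R_rows, r_vals = [], [], [], []

    for expr in _split_top(text):
        expr = _strip_outer_braces(expr)
        sides, ops = _split_relations(expr)
        if not ops:
            # a bare parameter list contributes no restriction rows
            for part in _members(sides[0]):
                _parse_linear(part, name_to_idx)  # validates names
            continue
        for left, op, right in zip(sides, ops, sides[1:]):
            if not left.strip() or not right.strip():
                raise ParseError(f"empty relation side in {expr!r}")
            lm, rm = _members(left), _members(right)
            if len(lm) > 1 and len(rm) > 1:
                raise ParseError(
                    f"brace sets on both sides of a relation in {expr!r}")
            for a in lm:
                for b in rm:
                    ca, ka = _parse_linear(a, name_to_idx)
                    cb, kb = _parse_linear(b, name_to_idx)
                    coefs, const = ca - cb, kb - ka
                    if op == "<":
                        coefs, const = -coefs, -const
                    if not np.any(coefs):
                        raise ParseError(
                            f"restriction without parameters in {expr!r}")
                    if op == "=":
                        S_rows.append(coefs)
                        s_vals.append(const)
                    else:
                        R_rows.append(coefs)
                        r_vals.append(const)

    k = len(eta_names)
    S = np.array(S_rows).reshape(-1, k)
    R = np.array(R_rows).reshape(-1, k)
    s = np.array(s_vals, dtype=float)
    r = np.array(r_vals, dtype=float)
    S, s = _normalize_rows(S, s)
    R, r = _normalize_rows(R, r)
    return LinearHypothesis(label, eta_names, S, s, R, r)


def _normalize_rows(m: np.ndarray, v: np.ndarray):
    """Sort rows lexicographically and drop exact duplicates."""
    if m.shape[0] == 0:
        return m, v
    keys = [tuple(row) + (c,) for row, c in zip(m, v)]
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    seen, keep = set(), []
    for i in order:
        if keys[i] not in seen:
            seen.add(keys[i])
            keep.append(i)
    return m[keep], v[keep]


def render(h: LinearHypothesis) -> str:
    """Render a hypothesis back to text; ``parse(render(h))`` is exact."""
    parts = []
    for row, c in zip(h.S, h.s):
        parts.append(f"{_render_combo(row, h.eta_names)} = {float(c)!r}")
    for row, c in zip(h.R, h.r):
        parts.append(f"{_render_combo(row, h.eta_names)} > {float(c)!r}")
    if not parts:
        return ", ".join(h.eta_names)
    return "; ".join(parts)


def _render_combo(row: np.ndarray, names) -> str:
    bits = []
    for coef, name in zip(row, names):
        if coef == 0:
            continue
        sign = "-" if coef < 0 else ("+" if bits else "")
        mag = float(abs(coef))
        term = name if mag == 1 else f"{mag!r}*{name}"
        bits.append(f"{sign} {term}" if bits else f"{sign}{term}")
    return " ".join(bits)


def relocate(h: LinearHypothesis) -> LinearHypothesis:
    """The homogeneous system (constants set to 0) used for the penalty."""
    return LinearHypothesis(h.label, list(h.eta_names), h.S.copy(),
                            np.zeros_like(h.s), h.R.copy(), np.zeros_like(h.r))


def parse_set(text: str, eta_names, include_unconstrained: bool = True
              ) -> HypothesisSet:
    """Parse a hypothesis file: one hypothesis per line, ``label: expr; ...``."""
    hyps = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ParseError(f"expected 'label: expressions', got {line!r}")
        label, body = line.split(":", 1)
        hyps.append(parse(body, eta_names, label=label.strip()))
    return HypothesisSet(hyps, include_unconstrained=include_unconstrained)


def load_packaged_set(name: str, eta_names) -> HypothesisSet:
    """Load a hypothesis set shipped with the package (``degrees`` or
    ``eyetracking``)."""
    fname = {"degrees": "degrees_hypotheses.txt",
             "eyetracking": "eyetracking_hypotheses.txt"}.get(name)
    if fname is None:
        raise KeyError(f"no packaged hypothesis set {name!r}")
    text = resources.files("goricatab.data").joinpath(fname).read_text()
    return parse_set(text, eta_names)
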