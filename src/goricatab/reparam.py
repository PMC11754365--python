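"""Reparameterizations eta = g(pi) of contingency-table cell probabilities.

Hypotheses on contingency tables are typically non-linear in the cell
probabilities (conditional probabilities, odds ratios).  Re-expressing them in
a vector of derived parameters eta — marginal sums, conditional proportions,
or cross-product ratios of cells — makes the restrictions linear in eta, so
the restricted fit becomes a quadratic program and the penalty becomes
invariant to the scale of the covariance matrix.

Every eta component is a quotient of products of cell-group sums::

    eta_k = prod_g sum(pi[num_g]) / prod_g sum(pi[den_g])

which covers all five restriction classes: plain cells and marginals (single
numerator group, empty denominator), conditional proportions (one group over
one group), and local/marginal/conditional odds ratios (two groups over two
groups, each group a cell or a marginal sum).

Sampling zeros make some components degenerate; this is reported through
per-component flags rather than errors:

* ``zero`` — the component evaluates to 0 with a positive denominator,
* ``one``  — a conditional proportion evaluates to 1 (no variation),
* ``inestimable`` — the denominator is 0 (the value is undefined).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .tables import ProbabilityVector

__all__ = [
    "EtaTerm",
    "EtaSpec",
    "EtaVector",
    "eta_value",
    "eta_matrix",
    "builtin_spec",
    "marginal_pattern_spec",
]

#: kinds whose components are proportions in [0, 1] (flag ``one`` applies)
CONDITIONAL_KINDS = frozenset({"conditional_row", "conditional_col", "custom_ratio"})
ODDS_KINDS = frozenset(
    {"local_odds_ratio", "marginal_odds_ratio", "conditional_odds_ratio"}
)
LINEAR_KINDS = frozenset({"cells", "marginal"})
ALL_KINDS = CONDITIONAL_KINDS | ODDS_KINDS | LINEAR_KINDS


@dataclass(frozen=True)
class EtaTerm:
    """One eta component: groups of flat cell indices to sum, then multiply.

    ``num``/``den`` are tuples of groups; each group is a tuple of flat cell
    indices whose probabilities are summed.  The term value is the product of
    the numerator group sums divided by the product of the denominator group
    sums (an empty ``den`` means divide by 1).
    """

    num: tuple[tuple[int, ...], ...]
    den: tuple[tuple[int, ...], ...] = ()


@dataclass
class EtaSpec:
    """A named reparameterization eta = g(pi) for a table of given dims."""

    kind: str
    dims: tuple[int, ...]
    terms: list[EtaTerm]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown reparameterization kind {self.kind!r}")
        self.dims = tuple(int(d) for d in self.dims)
        d_total = int(np.prod(self.dims))
        if not self.names:
            self.names = [f"eta{i + 1}" for i in range(len(self.terms))]
        if len(self.names) != len(self.terms):
            raise ValueError("one name per component required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("component names must be unique")
        for t in self.terms:
            for group in (*t.num, *t.den):
                for idx in group:
                    if not 0 <= idx < d_total:
                        raise ValueError(
                            f"cell index {idx} outside table with {d_total} cells"
                        )
            if self.kind in ODDS_KINDS and (len(t.num) != 2 or len(t.den) != 2):
                raise ValueError(
                    "odds-ratio components need a numerator pair and a "
                    "denominator pair of cell groups"
                )

    @property
    def k(self) -> int:
        return len(self.terms)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "dims": list(self.dims),
            "names": list(self.names),
            "terms": [
                {"num": [list(g) for g in t.num], "den": [list(g) for g in t.den]}
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EtaSpec":
        terms = [
            EtaTerm(
                tuple(tuple(g) for g in t["num"]),
                tuple(tuple(g) for g in t.get("den", [])),
            )
            for t in d["terms"]
        ]
        return cls(d["kind"], tuple(d["dims"]), terms, list(d.get("names", [])))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EtaSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "EtaSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class EtaVector:
    """Evaluated eta components with per-component degeneracy flags."""

    values: np.ndarray
    flags: list[str]
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def ok(self) -> bool:
        return all(f == "ok" for f in self.flags)

    @property
    def estimable(self) -> bool:
        return "inestimable" not in self.flags


def _group_sums(spec: EtaSpec, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Products of group sums for numerator and denominator, vectorized.

    ``p`` has shape (..., D); returns two arrays of shape (..., K).
    """
    nums = np.empty(p.shape[:-1] + (spec.k,))
    dens = np.empty_like(nums)
    for k, t in enumerate(spec.terms):
        v = np.ones(p.shape[:-1])
        for g in t.num:
            v = v * p[..., list(g)].sum(axis=-1)
        nums[..., k] = v
        w = np.ones(p.shape[:-1])
        for g in t.den:
            w = w * p[..., list(g)].sum(axis=-1)
        dens[..., k] = w
    return nums, dens


def eta_value(spec: EtaSpec, pi: ProbabilityVector) -> EtaVector:
    """Evaluate eta = g(pi) with degeneracy flags.

    Inestimable components (zero denominator) carry NaN as their value.
    """
    if tuple(pi.dims) != spec.dims:
        raise ValueError(f"spec dims {spec.dims} do not match table dims {pi.dims}")
    num, den = _group_sums(spec, pi.values)
    num, den = num.reshape(-1), den.reshape(-1)
    values = np.empty(spec.k)
    flags = []
    for k in range(spec.k):
        if den[k] == 0.0:
            values[k] = np.nan
            flags.append("inestimable")
            continue
        v = num[k] / den[k]
        values[k] = v
        if v == 0.0:
            flags.append("zero")
        elif v == 1.0 and spec.kind in CONDITIONAL_KINDS:
            flags.append("one")
        else:
            flags.append("ok")
    return EtaVector(values, flags, list(spec.names))


def eta_matrix(spec: EtaSpec, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate eta over a batch of probability vectors.

    Parameters
    ----------
    p
        Array of shape (B, D), rows on the simplex.

    Returns
    -------
    values : (B, K) array (NaN where inestimable)
    estimable : (B,) bool mask, True where all components have a positive
        denominator.
    """
    num, den = _group_sums(spec, np.asarray(p, dtype=float))
    estimable = (den > 0).all(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den > 0, num / np.where(den == 0, 1.0, den), np.nan)
    return values, estimable


# ---------------------------------------------------------------------------
# builtin families
# ---------------------------------------------------------------------------

def _flat(dims, idx) -> int:
    return int(np.ravel_multi_index(idx, dims))


def _marginal_group(dims, pattern) -> tuple[int, ...]:
    """Flat indices of cells matching a pattern with ``None`` = summed axis."""
    axes = [range(d) if lv is None else [lv] for lv, d in zip(pattern, dims)]
    return tuple(_flat(dims, idx) for idx in np.array(
        np.meshgrid(*axes, indexing="ij")).reshape(len(dims), -1).T)


def marginal_pattern_spec(dims, patterns, names=None) -> EtaSpec:
    """Marginal probabilities by pattern, e.g. ``(0, 0, None)`` for pi_11+.

    ``None`` entries are summed over; fixed entries are 0-based levels.
    """
    terms = [EtaTerm((_marginal_group(dims, pat),)) for pat in patterns]
    return EtaSpec("marginal", tuple(dims), terms, list(names or []))


def builtin_spec(kind: str, dims, *, axis: int = 0, level: int | None = None,
                 fixed_axis: int | None = None,
                 fixed_level: int = 0) -> EtaSpec:
    """Generate a full eta family in the adjacent-cell convention.

    Parameters
    ----------
    kind
        One of ``cells``, ``marginal``, ``conditional_row``,
        ``conditional_col``, ``local_odds_ratio``, ``marginal_odds_ratio``,
        ``conditional_odds_ratio``.
    axis
        For ``marginal``: the factor whose levels index the components.
        For ``marginal_odds_ratio``: the factor summed over.
    level
        For ``conditional_row``: the focus level of the first factor (default
        last); components are eta_j = pi[level, j] / pi[+, j].
        For ``conditional_col``: the focus level of the second factor;
        components are eta_i = pi[i, level] / pi[i, +].
    fixed_axis, fixed_level
        For ``conditional_odds_ratio``: the factor and level held fixed; one
        spec is generated per fixed level (build several for the full family).
    """
    dims = tuple(int(d) for d in dims)
    nd = len(dims)

    if kind == "cells":
        terms = [EtaTerm(((i,),)) for i in range(int(np.prod(dims)))]
        return EtaSpec("cells", dims, terms)

    if kind == "marginal":
        patterns = []
        for lv in range(dims[axis]):
            pat = [None] * nd
            pat[axis] = lv
            patterns.append(tuple(pat))
        terms = [EtaTerm((_marginal_group(dims, pat),)) for pat in patterns]
        return EtaSpec("marginal", dims, terms)

    if kind == "conditional_row":
        if nd != 2:
            raise ValueError("conditional_row needs a two-way table")
        i = dims[0] - 1 if level is None else level
        terms = []
        for j in range(dims[1]):
            num = ((_flat(dims, (i, j)),),)
            den = ((tuple(_flat(dims, (r, j)) for r in range(dims[0]))),)
            terms.append(EtaTerm(num, (den[0],)))
        return EtaSpec("conditional_row", dims, terms)

    if kind == "conditional_col":
        if nd != 2:
            raise ValueError("conditional_col needs a two-way table")
        j = dims[1] - 1 if level is None else level
        terms = []
        for i in range(dims[0]):
            num = ((_flat(dims, (i, j)),),)
            den = tuple(_flat(dims, (i, c)) for c in range(dims[1]))
            terms.append(EtaTerm(num, (den,)))
        return EtaSpec("conditional_col", dims, terms)

    if kind == "local_odds_ratio":
        if nd != 2:
            raise ValueError("local odds ratios need a two-way table")
        terms = []
        for i in range(1, dims[0]):
            for j in range(1, dims[1]):
                # cells (i-1, j-1), (i, j) over (i-1, j), (i, j-1)
                terms.append(EtaTerm(
                    (((_flat(dims, (i - 1, j - 1)),)), ((_flat(dims, (i, j)),))),
                    (((_flat(dims, (i - 1, j)),)), ((_flat(dims, (i, j - 1)),))),
                ))
        return EtaSpec("local_odds_ratio", dims, terms)

    if kind == "marginal_odds_ratio":
        if nd < 3:
            raise ValueError("marginal odds ratios need >= 3 factors")
        keep = [a for a in range(nd) if a != axis]
        da, db = dims[keep[0]], dims[keep[1]]

        def pat(la, lb):
            p = [None] * nd
            p[keep[0]], p[keep[1]] = la, lb
            return tuple(p)

        terms = []
        for a in range(1, da):
            for b in range(1, db):
                terms.append(EtaTerm(
                    (_marginal_group(dims, pat(a - 1, b - 1)),
                     _marginal_group(dims, pat(a, b))),
                    (_marginal_group(dims, pat(a - 1, b)),
                     _marginal_group(dims, pat(a, b - 1))),
                ))
        return EtaSpec("marginal_odds_ratio", dims, terms)

    if kind == "conditional_odds_ratio":
        if nd < 3:
            raise ValueError("conditional odds ratios need >= 3 factors")
        fa = fixed_axis if fixed_axis is not None else nd - 1
        keep = [a for a in range(nd) if a != fa]
        da, db = dims[keep[0]], dims[keep[1]]

        def cell(la, lb):
            idx = [0] * nd
            idx[fa] = fixed_level
            idx[keep[0]], idx[keep[1]] = la, lb
            return (_flat(dims, tuple(idx)),)

        terms = []
        for a in range(1, da):
            for b in range(1, db):
                terms.append(EtaTerm(
                    (cell(a - 1, b - 1), cell(a, b)),
                    (cell(a - 1, b), cell(a, b - 1)),
                ))
        return EtaSpec("conditional_odds_ratio", dims, terms)

    raise ValueError(f"unknown builtin kind {kind!r}")
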