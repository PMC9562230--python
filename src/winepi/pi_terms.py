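"""Dimensionless Pi-forms over a modulator's variables.

A Pi-form is a rational expression ``numerator / denominator`` over the
positive variables ``x1 .. xk`` of one flavour modulator, restricted to two
expression kinds:

* a *sum* of distinct variables, e.g. ``x1 + x2`` (every term has degree 1);
* a *monomial* with positive integer exponents, e.g. ``x1 * x3**2``.

All variables within a modulator share one unit (concentrations in ug/L), so
an expression is dimensionless exactly when the total degree of the numerator
equals the total degree of the denominator.  That degree balance is the
dimensional-homogeneity check of the Buckingham Pi construction, and it is
equivalent to scale invariance: a homogeneous form evaluates identically on
``x`` and ``c * x`` for any ``c > 0``.

Forms serialise to a compact text notation -- ``(x1+x2)/x3``, ``x1*x3/x2^2``,
``x3/(x1+x2)`` -- which doubles as their stable identifier.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PiForm",
    "PiTerm",
    "PiFormError",
    "parse_pi_form",
    "enumerate_pi_forms",
    "check_homogeneity",
    "evaluate_pi",
]


class PiFormError(ValueError):
    """Raised for malformed, non-homogeneous, or non-positive-input forms."""


# An expression is ("sum", (i, j, ...)) for x_i + x_j + ... (distinct indices),
# or ("mono", ((i, e), ...)) for prod x_i**e with e >= 1, indices sorted.
Expr = tuple[str, tuple]


def _sum_expr(indices: Iterable[int]) -> Expr:
    idx = tuple(sorted(set(int(i) for i in indices)))
    if len(idx) < 2:
        raise PiFormError("a sum expression needs at least two distinct variables")
    return ("sum", idx)


def _mono_expr(powers: Mapping[int, int]) -> Expr:
    items = tuple(sorted((int(i), int(e)) for i, e in powers.items() if e != 0))
    if not items:
        raise PiFormError("a monomial expression needs at least one variable")
    if any(e < 0 for _, e in items):
        raise PiFormError("monomial exponents must be positive integers")
    return ("mono", items)


def _expr_degree(expr: Expr) -> int:
    kind, body = expr
    if kind == "sum":
        return 1
    return sum(e for _, e in body)


def _expr_vars(expr: Expr) -> set[int]:
    kind, body = expr
    if kind == "sum":
        return set(body)
    return {i for i, _ in body}


def _expr_text(expr: Expr, *, parenthesise: bool) -> str:
    kind, body = expr
    if kind == "sum":
        text = "+".join(f"x{i}" for i in body)
        return f"({text})"
    factors = []
    for i, e in body:
        factors.append(f"x{i}" if e == 1 else f"x{i}^{e}")
    text = "*".join(factors)
    if parenthesise and len(body) > 1:
        return f"({text})"
    return text


def _expr_value(expr: Expr, values: Mapping[int, float]) -> float:
    kind, body = expr
    if kind == "sum":
        return float(sum(values[i] for i in body))
    out = 1.0
    for i, e in body:
        out *= float(values[i]) ** e
    return out


@dataclass(frozen=True)
class PiForm:
    """A rational expression over modulator variables.

    The ``id`` is the canonical text notation and is what configs and result
    manifests store.
    """

    numerator: Expr
    denominator: Expr
    id: str = field(init=False)

    def __post_init__(self) -> None:
        for expr in (self.numerator, self.denominator):
            kind = expr[0]
            if kind not in ("sum", "mono"):
                raise PiFormError(f"unknown expression kind {kind!r}")
        object.__setattr__(self, "id", self._notation())

    def _notation(self) -> str:
        num = _expr_text(self.numerator, parenthesise=False)
        den = _expr_text(self.denominator, parenthesise=True)
        return f"{num}/{den}"

    @property
    def variables(self) -> set[int]:
        return _expr_vars(self.numerator) | _expr_vars(self.denominator)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.id


@dataclass(frozen=True)
class PiTerm:
    """An evaluated Pi-form: the dimensionless value fed to the quality model."""

    form: PiForm
    value: float

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise PiFormError(f"pi value must be positive, got {self.value}")


_MONO_FACTOR = re.compile(r"^x(\d+)(?:\^(\d+))?$")


def _parse_expr(text: str) -> Expr:
    text = text.strip()
    if text.startswith("(") and text.endswith(")"):
        text = text[1:-1].strip()
    if "+" in text:
        indices = []
        for part in text.split("+"):
            m = _MONO_FACTOR.match(part.strip())
            if m is None or m.group(2) is not None:
                raise PiFormError(f"cannot parse sum term {part!r}")
            indices.append(int(m.group(1)))
        return _sum_expr(indices)
    powers: dict[int, int] = {}
    for part in text.split("*"):
        m = _MONO_FACTOR.match(part.strip())
        if m is None:
            raise PiFormError(f"cannot parse monomial factor {part!r}")
        i = int(m.group(1))
        e = int(m.group(2) or 1)
        powers[i] = powers.get(i, 0) + e
    return _mono_expr(powers)


def parse_pi_form(text: str) -> PiForm:
    """Parse the compact notation, e.g. ``(x1+x2)/x3`` or ``x1*x3/x2^2``.

    The slash splitting respects a single parenthesised group on either side;
    nested parentheses are not part of the notation.
    """
    text = text.strip()
    depth = 0
    slash = -1
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "/" and depth == 0:
            if slash != -1:
                raise PiFormError(f"multiple top-level '/' in {text!r}")
            slash = pos
    if slash == -1:
        raise PiFormError(f"pi-form notation needs a '/': {text!r}")
    return PiForm(_parse_expr(text[:slash]), _parse_expr(text[slash + 1 :]))


def check_homogeneity(form: PiForm) -> bool:
    """True iff the form is dimensionless (numerator and denominator share
    the same total degree; every additive term already has degree 1 by
    construction)."""
    return _expr_degree(form.numerator) == _expr_degree(form.denominator)


def evaluate_pi(form: PiForm, values: Sequence[float] | Mapping[int, float]) -> PiTerm:
    """Evaluate a homogeneous form on strictly positive variable values.

    ``values`` may be a sequence (position 0 is ``x1``) or a mapping from the
    1-based variable index.  Non-homogeneous forms are rejected before any
    arithmetic, and non-positive inputs raise a domain error.
    """
    if not check_homogeneity(form):
        raise PiFormError(f"form {form.id} is not dimensionally homogeneous")
    if isinstance(values, Mapping):
        lookup = {int(i): float(v) for i, v in values.items()}
    else:
        lookup = {i + 1: float(v) for i, v in enumerate(values)}
    for i in form.variables:
        if i not in lookup:
            raise PiFormError(f"form {form.id} needs x{i}, not provided")
        if not (lookup[i] > 0):
            raise PiFormError(f"x{i} must be strictly positive, got {lookup[i]}")
    value = _expr_value(form.numerator, lookup) / _expr_value(form.denominator, lookup)
    return PiTerm(form, value)


def _monomial_vectors(k_vars: int, degree: int) -> list[tuple[int, ...]]:
    """All exponent vectors over k_vars variables with the given total degree."""
    out = []
    for combo in itertools.combinations_with_replacement(range(k_vars), degree):
        vec = [0] * k_vars
        for i in combo:
            vec[i] += 1
        out.append(tuple(vec))
    return out


def enumerate_pi_forms(
    k_vars: int = 3,
    max_degree: int = 2,
    include_sums: bool = True,
) -> list[PiForm]:
    """Enumerate every admissible dimensionless form over ``k_vars`` variables.

    Two families are generated:

    * additive -- ``(xi+xj)/xl`` and ``xl/(xi+xj)`` for every unordered pair
      ``{i, j}`` and every third variable ``l`` outside the pair (degree 1 on
      both sides);
    * monomial -- ``prod x^a / prod x^b`` for every pair of exponent vectors
      with disjoint support and equal total degree between 1 and
      ``max_degree``.

    Every returned form passes :func:`check_homogeneity`; ids are canonical
    and the list is sorted by id, so enumeration order is stable across runs.
    """
    if k_vars < 2:
        raise PiFormError("need at least two variables to form a dimensionless group")
    if max_degree < 1:
        raise PiFormError("max_degree must be at least 1")
    forms: list[PiForm] = []
    if include_sums:
        for pair in itertools.combinations(range(1, k_vars + 1), 2):
            for l in range(1, k_vars + 1):
                if l in pair:
                    continue
                s = _sum_expr(pair)
                v = _mono_expr({l: 1})
                forms.append(PiForm(s, v))
                forms.append(PiForm(v, s))
    for degree in range(1, max_degree + 1):
        vectors = _monomial_vectors(k_vars, degree)
        for num_vec in vectors:
            for den_vec in vectors:
                if any(a > 0 and b > 0 for a, b in zip(num_vec, den_vec)):
                    continue  # shared variable: not in canonical form
                num = {i + 1: e for i, e in enumerate(num_vec) if e}
                den = {i + 1: e for i, e in enumerate(den_vec) if e}
                forms.append(PiForm(_mono_expr(num), _mono_expr(den)))
    forms.sort(key=lambda f: f.id)
    assert all(check_homogeneity(f) for f in forms)
    return forms
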