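"""Triangular fuzzy numbers and linguistic rating scales.

The whole framework runs on triangular fuzzy numbers (TFNs): a TFN
``(a, b, c)`` with ``a <= b <= c`` models an uncertain quantity whose
membership rises linearly from ``a`` to a peak at ``b`` and falls back to
zero at ``c``.  Expert Likert ratings and linguistic difference judgements
are mapped onto five-term TFN scales, combined with extension-principle
arithmetic, and collapsed back to crisp numbers by centroid
defuzzification ``(a + b + c) / 3``.

Only non-negative TFNs are supported: every built-in scale lives in
``[0, 1]``, and restricting to non-negative supports keeps subtraction and
division well-ordered (``a <= b <= c`` is preserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "TFN",
    "LinguisticScale",
    "IMPORTANCE5",
    "DIFFERENCE5",
    "SCALE_REGISTRY",
    "likert_to_tfn",
    "tfn_mean",
    "load_scale",
]

_ORDER_TOL = 1e-9


@dataclass(frozen=True)
class TFN:
    """A non-negative triangular fuzzy number ``(a, b, c)``, ``a <= b <= c``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c):
            if not math.isfinite(v):
                raise ValueError(f"TFN components must be finite, got {self!r}")
        if self.a < -_ORDER_TOL:
            raise ValueError(f"TFN components must be non-negative, got {self!r}")
        if not (self.a <= self.b + _ORDER_TOL and self.b <= self.c + _ORDER_TOL):
            raise ValueError(f"TFN ordering a <= b <= c violated: {self!r}")

    # -- extension-principle arithmetic (componentwise rules) ------------

    def __add__(self, other: "TFN") -> "TFN":
        return TFN(self.a + other.a, self.b + other.b, self.c + other.c)

    def __sub__(self, other: "TFN") -> "TFN":
        # (a1-c2, b1-b2, c1-a2); may leave the non-negative cone, in which
        # case the TFN constructor raises.
        return TFN(self.a - other.c, self.b - other.b, self.c - other.a)

    def __mul__(self, other):
        if isinstance(other, TFN):
            return TFN(self.a * other.a, self.b * other.b, self.c * other.c)
        return self.scale(float(other))

    __rmul__ = __mul__

    def __truediv__(self, other: "TFN") -> "TFN":
        return self * other.inverse()

    def scale(self, alpha: float) -> "TFN":
        """Scalar multiple ``alpha * (a, b, c)`` for ``alpha >= 0``."""
        if alpha < 0:
            raise ValueError(f"scalar must be non-negative, got {alpha}")
        return TFN(alpha * self.a, alpha * self.b, alpha * self.c)

    def inverse(self) -> "TFN":
        """Fuzzy reciprocal ``(1/c, 1/b, 1/a)``; requires a > 0."""
        if self.a <= 0:
            raise ValueError(
                f"cannot invert TFN with non-positive component: {self!r}"
            )
        return TFN(1.0 / self.c, 1.0 / self.b, 1.0 / self.a)

    def membership(self, x: float) -> float:
        """Degree of membership of the crisp value ``x`` in this TFN.

        Piecewise linear: 0 outside ``[a, c]``, rising on ``[a, b]``,
        falling on ``[b, c]``, exactly 1 at ``x == b``.  Degenerate edges
        (``b == a`` or ``b == c``) are treated as steps so the peak keeps
        membership 1 (continuity limit of the linear edge).
        """
        if x < self.a or x > self.c:
            return 0.0
        if x == self.b:
            return 1.0
        if x < self.b:
            return (x - self.a) / (self.b - self.a)
        if self.c == self.b:  # degenerate right edge, x > b already excluded above
            return 1.0
        return (self.c - x) / (self.c - self.b)

    def defuzzify(self) -> float:
        """Centroid defuzzification ``(a + b + c) / 3``."""
        return (self.a + self.b + self.c) / 3.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def tfn_mean(tfns: Sequence[TFN]) -> TFN:
    """Componentwise arithmetic mean of a non-empty sequence of TFNs."""
    if len(tfns) == 0:
        raise ValueError("cannot average an empty sequence of TFNs")
    n = len(tfns)
    return TFN(
        sum(t.a for t in tfns) / n,
        sum(t.b for t in tfns) / n,
        sum(t.c for t in tfns) / n,
    )


@dataclass(frozen=True)
class LinguisticScale:
    """An ordered five-term linguistic scale mapped to TFNs.

    ``terms`` is an ordered tuple of ``(label, code, TFN)`` with integer
    codes 1..n; TFN modes must strictly increase along the scale.
    """

    name: str
    terms: tuple[tuple[str, int, TFN], ...]

    def __post_init__(self) -> None:
        modes = [t.b for (_, _, t) in self.terms]
        if any(m2 <= m1 for m1, m2 in zip(modes, modes[1:])):
            raise ValueError(
                f"scale {self.name!r}: TFN modes must strictly increase"
            )
        codes = [code for (_, code, _) in self.terms]
        if codes != list(range(1, len(self.terms) + 1)):
            raise ValueError(f"scale {self.name!r}: codes must be 1..n in order")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for (label, _, _) in self.terms)

    def tfn_for_code(self, code: int) -> TFN:
        for _, c, t in self.terms:
            if c == code:
                return t
        raise ValueError(
            f"code {code} outside scale {self.name!r} (valid: 1..{len(self.terms)})"
        )

    def tfn_for_label(self, label: str) -> TFN:
        """Look up a term by label (case-insensitive); accepts numeric codes."""
        needle = str(label).strip().lower()
        for lab, code, t in self.terms:
            if lab.lower() == needle or str(code) == needle:
                return t
        raise ValueError(f"unknown term {label!r} for scale {self.name!r}")


# Five-level TFN vocabulary shared by the importance and difference scales.
_FIVE_TFNS = (
    TFN(0.00, 0.10, 0.30),
    TFN(0.10, 0.30, 0.50),
    TFN(0.30, 0.50, 0.75),
    TFN(0.50, 0.75, 0.90),
    TFN(0.75, 0.90, 1.00),
)

#: Expert feature-importance scale (five-point Likert).
IMPORTANCE5 = LinguisticScale(
    "importance5",
    tuple(
        (label, i + 1, t)
        for i, (label, t) in enumerate(
            zip(
                (
                    "Not important",
                    "Slight important",
                    "Moderately important",
                    "Important",
                    "Very important",
                ),
                _FIVE_TFNS,
            )
        )
    ),
)

#: Difference-from-ideal scale used when ranking alternatives.
DIFFERENCE5 = LinguisticScale(
    "difference5",
    tuple(
        (label, i + 1, t)
        for i, (label, t) in enumerate(
            zip(
                (
                    "No difference",
                    "Slight difference",
                    "Difference",
                    "Big difference",
                    "Huge difference",
                ),
                _FIVE_TFNS,
            )
        )
    ),
)

SCALE_REGISTRY: dict[str, LinguisticScale] = {
    IMPORTANCE5.name: IMPORTANCE5,
    DIFFERENCE5.name: DIFFERENCE5,
}


def likert_to_tfn(level: int, scale: LinguisticScale = IMPORTANCE5) -> TFN:
    """Map an integer Likert level (1-5) to its TFN on ``scale``.

    Raises ``ValueError`` for non-integer or out-of-range levels; fractional
    ratings are rejected rather than rounded because the scale is defined
    only on integer codes.
    """
    if not float(level).is_integer():
        raise ValueError(f"Likert level must be an integer, got {level!r}")
    level = int(level)
    if not 1 <= level <= len(scale.terms):
        raise ValueError(
            f"Likert level {level} outside scale {scale.name!r} range "
            f"1..{len(scale.terms)}"
        )
    return scale.tfn_for_code(level)


def load_scale(name: str, rows: Iterable[Sequence]) -> LinguisticScale:
    """Build a scale from config rows ``(label, code, a, b, c)`` and register it."""
    terms = tuple(
        (str(label), int(code), TFN(float(a), float(b), float(c)))
        for label, code, a, b, c in rows
    )
    scale = LinguisticScale(name, terms)
    SCALE_REGISTRY[name] = scale
    return scale
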