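"""Rate sets and equality-constraint patterns for the BiSSE model.

BiSSE describes a lineage evolving a binary character (states 0 and 1)
while diversifying: state-specific speciation rates ``lambda0``/``lambda1``,
extinction rates ``mu0``/``mu1`` and character transition rates ``q01``
(0 to 1) and ``q10`` (1 to 0), all in events per lineage per unit time.

Constrained models (3-6 free parameters) are expressed as partitions of the
six rate names into equality classes; only rates of the same process
(speciation with speciation, etc.) may be merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

RATE_NAMES = ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10")

#: which process each rate belongs to
_PROCESS = {
    "lambda0": "speciation",
    "lambda1": "speciation",
    "mu0": "extinction",
    "mu1": "extinction",
    "q01": "character_change",
    "q10": "character_change",
}

PROCESSES = ("speciation", "extinction", "character_change")

#: short aliases accepted in compact pattern strings, e.g. "l0,l1,m=,q="
_ALIAS = {"l": "lambda", "m": "mu", "q": "q"}


class RateValidationError(ValueError):
    """A rate set or constraint pattern violates its invariants."""


@dataclass(frozen=True)
class RateSet:
    """The six BiSSE rates.

    All rates must be finite and non-negative, and at least one speciation
    rate must be positive (otherwise no tree can grow).
    """

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise RateValidationError(f"rate {name} must be finite, got {v!r}")
            if v < 0:
                raise RateValidationError(f"rate {name} must be >= 0, got {v!r}")
        if self.lambda0 <= 0 and self.lambda1 <= 0:
            raise RateValidationError("at least one speciation rate must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in RATE_NAMES}

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RateSet":
        values = list(values)
        if len(values) != 6:
            raise RateValidationError(f"expected 6 rates, got {len(values)}")
        return cls(*map(float, values))

    def swapped(self) -> "RateSet":
        """Relabel the character states (0 <-> 1)."""
        return RateSet(self.lambda1, self.lambda0, self.mu1, self.mu0,
                       self.q10, self.q01)

    def process_rates(self, process: str) -> tuple[float, float]:
        if process == "speciation":
            return self.lambda0, self.lambda1
        if process == "extinction":
            return self.mu0, self.mu1
        if process == "character_change":
            return self.q01, self.q10
        raise ValueError(f"unknown process {process!r}")

    def replace(self, **kw: float) -> "RateSet":
        d = self.as_dict()
        d.update(kw)
        return RateSet(**d)


class ConstraintPattern:
    """A partition of the six rate names into equality classes.

    Each class holds one free parameter; rates in the same class are forced
    equal. Only same-process rates may share a class, which is exactly the
    family of 3- to 6-parameter models used in BiSSE hypothesis tests.
    """

    def __init__(self, classes: Iterable[Iterable[str]]):
        cls_list: list[tuple[str, ...]] = []
        seen: set[str] = set()
        for c in classes:
            members = tuple(c)
            if not members:
                raise RateValidationError("empty equality class")
            for name in members:
                if name not in RATE_NAMES:
                    raise RateValidationError(f"unknown rate name {name!r}")
                if name in seen:
                    raise RateValidationError(f"rate {name!r} appears twice")
                seen.add(name)
            procs = {_PROCESS[m] for m in members}
            if len(procs) > 1:
                raise RateValidationError(
                    f"cannot merge rates across processes: {members}")
            # canonical member order
            members = tuple(sorted(members, key=RATE_NAMES.index))
            cls_list.append(members)
        if seen != set(RATE_NAMES):
            missing = set(RATE_NAMES) - seen
            raise RateValidationError(f"rates missing from pattern: {sorted(missing)}")
        # canonical class order: by first member's position
        cls_list.sort(key=lambda m: RATE_NAMES.index(m[0]))
        self.classes: tuple[tuple[str, ...], ...] = tuple(cls_list)

    @property
    def free_count(self) -> int:
        return len(self.classes)

    @property
    def free_names(self) -> tuple[str, ...]:
        """One representative name per equality class."""
        return tuple(c[0] for c in self.classes)

    # -- constructors for the model family used in the study ---------------

    @classmethod
    def full(cls) -> "ConstraintPattern":
        """The unconstrained six-parameter model."""
        return cls([(n,) for n in RATE_NAMES])

    @classmethod
    def constrained(cls, process: str) -> "ConstraintPattern":
        """Five-parameter model: the given process symmetric, others free."""
        pair = _process_pair(process)
        classes = [[n for n in pair]] + [[n] for n in RATE_NAMES if n not in pair]
        return cls(classes)

    @classmethod
    def reduced_full(cls, process: str) -> "ConstraintPattern":
        """Four-parameter model: only the given process free (asymmetric)."""
        pair = _process_pair(process)
        classes = [[n] for n in pair]
        for p in PROCESSES:
            if p != process:
                classes.append(list(_process_pair(p)))
        return cls(classes)

    @classmethod
    def reduced_null(cls) -> "ConstraintPattern":
        """Three-parameter model: every process symmetric."""
        return cls([list(_process_pair(p)) for p in PROCESSES])

    @classmethod
    def from_string(cls, text: str) -> "ConstraintPattern":
        """Parse a compact pattern like ``"l0,l1,m=,q="``.

        Tokens: ``l0``/``l1``/``m0``/``m1``/``q0``/``q1`` declare a free
        rate; ``l=``/``m=``/``q=`` merge the process's two rates.
        """
        classes: list[list[str]] = []
        for tok in text.replace(" ", "").split(","):
            if not tok:
                continue
            if len(tok) != 2 or tok[0] not in _ALIAS:
                raise RateValidationError(f"bad pattern token {tok!r}")
            stem = _ALIAS[tok[0]]
            pair = [f"{stem}0", f"{stem}1"] if stem != "q" else ["q01", "q10"]
            if tok[1] == "=":
                classes.append(pair)
            elif tok[1] in "01":
                classes.append([pair[int(tok[1])]])
            else:
                raise RateValidationError(f"bad pattern token {tok!r}")
        return cls(classes)

    def to_string(self) -> str:
        toks = []
        for c in self.classes:
            stem = c[0][0]  # 'l', 'm' or 'q'
            if len(c) == 2:
                toks.append(f"{stem}=")
            else:
                suffix = "0" if c[0] in ("lambda0", "mu0", "q01") else "1"
                toks.append(f"{stem}{suffix}")
        return ",".join(toks)

    def nests_in(self, full: "ConstraintPattern") -> bool:
        """True if this (more constrained) pattern nests in ``full``: every
        class here is a union of classes of ``full``."""
        # both are partitions of the same six names, so nesting is
        # equivalent to: every class of the fuller pattern lies inside
        # some class of this one
        return all(
            any(set(fc) <= set(c) for c in self.classes) for fc in full.classes
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConstraintPattern) and self.classes == other.classes

    def __hash__(self) -> int:
        return hash(self.classes)

    def __repr__(self) -> str:
        return f"ConstraintPattern({self.to_string()!r})"


def _process_pair(process: str) -> tuple[str, str]:
    if process == "speciation":
        return ("lambda0", "lambda1")
    if process == "extinction":
        return ("mu0", "mu1")
    if process == "character_change":
        return ("q01", "q10")
    raise ValueError(f"unknown process {process!r}; expected one of {PROCESSES}")


def expand_params(free_values: Sequence[float], pattern: ConstraintPattern) -> RateSet:
    """Map a vector of free parameters (one per equality class) to a RateSet."""
    free_values = list(free_values)
    if len(free_values) != pattern.free_count:
        raise RateValidationError(
            f"expected {pattern.free_count} values, got {len(free_values)}")
    d: dict[str, float] = {}
    for value, members in zip(free_values, pattern.classes):
        if value < 0:
            raise RateValidationError(f"negative rate value {value!r}")
        for name in members:
            d[name] = float(value)
    return RateSet(**d)


def project_params(rates: RateSet, pattern: ConstraintPattern) -> np.ndarray:
    """Inverse of :func:`expand_params`: one value per class (the first
    member's value; other members are overwritten on expansion)."""
    return np.array([getattr(rates, c[0]) for c in pattern.classes], dtype=float)
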