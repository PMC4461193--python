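"""Isotopic stick patterns for arbitrary molecular formulas and charge states.

An element is a list of (exact mass, natural abundance) pairs; a molecule's
isotopic pattern is the convolution of its elements' patterns.  Because the
number of isotopologues of a homonuclear molecule E_nu grows like nu**N_I,
two controlled approximations are applied between convolution steps:

* sticks below an abundance threshold ``eps_a`` are dropped (no
  renormalisation afterwards), and
* sticks closer than a mass threshold ``eps_m`` — unresolvable at the
  instrument's resolution — are merged into a single stick at their
  abundance-weighted centre of mass.

Multiply charged ions (charge ``z``) appear at 1/z of their neutral mass;
stick masses are divided by z after convolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ELECTRON_MASS_DA",
    "ElementRecord",
    "IsotopePattern",
    "Formula",
    "PruneConfig",
    "FormulaError",
    "register_element",
    "get_element",
    "known_elements",
    "load_element_table",
    "parse_formula",
    "element_pattern",
    "convolve",
    "prune_low",
    "merge_close",
    "pattern_power",
    "species_pattern",
    "expand_series",
]

ELECTRON_MASS_DA = 5.48579909e-4


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementRecord:
    """An element's isotopes: masses strictly increasing, abundances sum to 1."""

    symbol: str
    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "abundances", a)
        if m.ndim != 1 or a.shape != m.shape or m.size == 0:
            raise ValueError(f"{self.symbol}: masses/abundances must be matching 1-D arrays")
        if not np.all(np.diff(m) > 0):
            raise ValueError(f"{self.symbol}: isotope masses must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError(f"{self.symbol}: abundances must all be > 0")
        if abs(a.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.symbol}: abundances sum to {a.sum():.8f}, expected 1")

    @classmethod
    def from_pairs(cls, symbol: str, pairs: Iterable[tuple[float, float]]) -> "ElementRecord":
        pairs = sorted(pairs)
        return cls(symbol, np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))


@dataclass(frozen=True)
class IsotopePattern:
    """A stick spectrum: sorted (mass, abundance) pairs with abundances > 0.

    Masses are in Da for neutral/singly-charged species, or Th (m/z) after
    charge division.  The abundance sum is 1 when no pruning has been applied
    and at most 1 otherwise.
    """

    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "abundances", a)
        if m.ndim != 1 or a.shape != m.shape:
            raise ValueError("masses/abundances must be matching 1-D arrays")
        if m.size and not np.all(np.diff(m) > 0):
            raise ValueError("stick masses must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("stick abundances must be > 0")

    def __len__(self) -> int:
        return int(self.masses.size)

    @property
    def total_abundance(self) -> float:
        return float(self.abundances.sum())

    @property
    def mean_mass(self) -> float:
        """Abundance-weighted mean stick mass."""
        return float(np.average(self.masses, weights=self.abundances))

    def sticks(self) -> list[tuple[float, float]]:
        return list(zip(self.masses.tolist(), self.abundances.tolist()))

    @classmethod
    def from_sticks(cls, sticks: Iterable[tuple[float, float]]) -> "IsotopePattern":
        sticks = sorted(sticks)
        return cls(np.array([s[0] for s in sticks]), np.array([s[1] for s in sticks]))


@dataclass(frozen=True)
class Formula:
    """A parsed molecular formula: flattened element counts plus charge.

    ``components`` preserves first-appearance order of the element symbols;
    ``groups`` preserves the top-level grouping as written, for labelling
    cluster series (e.g. ``(C60)3Na12`` -> [("C60", 3), ("Na", 12)]).
    """

    components: tuple[tuple[str, int], ...]
    charge: int = 1
    label: str = ""
    groups: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not self.components:
            raise ValueError("formula has no components")
        for sym, n in self.components:
            if n < 1:
                raise ValueError(f"count for {sym} must be >= 1")

    def as_dict(self) -> dict[str, int]:
        return dict(self.components)


@dataclass(frozen=True)
class PruneConfig:
    """Thresholds for the two pattern approximations.

    eps_a: sticks with abundance < eps_a are dropped (default 1e-10).
    eps_m: successive sticks closer than eps_m Da are merged (default 0,
           i.e. only exact mass collisions combine).  A practical choice is
           FWHM/5 at the species' nominal mass.
    """

    eps_a: float = 1e-10
    eps_m: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps_a < 1.0):
            raise ValueError("eps_a must be in [0, 1)")
        if self.eps_m < 0.0:
            raise ValueError("eps_m must be >= 0")


EXACT = PruneConfig(eps_a=0.0, eps_m=0.0)

#: Floating-point collision floor for convolution (Da): the same
#: isotopologue reached through different summation orders lands within
#: ~1e-10 Da of itself; any physical stick separation is >= ~1e-4 Da.
FP_MERGE_EPS_DA = 1e-9


# ---------------------------------------------------------------------------
# Element registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, ElementRecord] = {}


def load_element_table(path=None) -> dict[str, ElementRecord]:
    """Load an isotope table (tab/whitespace separated: symbol, mass, abundance).

    With no path, loads the bundled standard table.  Returns the records
    without touching the global registry.
    """
    if path is None:
        text = resources.files("isodecomp.data").joinpath("elements.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows: dict[str, list[tuple[float, float]]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"element table line {lineno}: expected 3 columns, got {len(parts)}")
        sym, mass, ab = parts[0], float(parts[1]), float(parts[2])
        rows.setdefault(sym, []).append((mass, ab))
    return {sym: ElementRecord.from_pairs(sym, pairs) for sym, pairs in rows.items()}


def _ensure_registry() -> dict[str, ElementRecord]:
    if not _REGISTRY:
        _REGISTRY.update(load_element_table())
    return _REGISTRY


def register_element(record: ElementRecord) -> None:
    """Register (or override) an element at runtime, e.g. an artificial atom."""
    _ensure_registry()[record.symbol] = record


def get_element(symbol: str) -> ElementRecord:
    reg = _ensure_registry()
    try:
        return reg[symbol]
    except KeyError:
        raise FormulaError(f"unknown element symbol {symbol!r}") from None


def known_elements() -> list[str]:
    return sorted(_ensure_registry())


# ---------------------------------------------------------------------------
# Formula grammar
# ---------------------------------------------------------------------------
#
#   Formula := '[' Body ']' Charge? | Body ( WS Digits '+' | '+'+ )?
#   Body    := ( Element Count? | '(' Body ')' Count? )+
#   Element := [A-Z][a-z]?
#   Count   := [0-9]+
#   Charge  := Digits? '+'+
#
# A charge written as digits ("2+") must follow the closing ']' or be
# whitespace-separated from the body; repeated '+' signs also count
# ("C40++" is doubly charged).  Default charge is 1.

_ELEMENT_RE = re.compile(r"[A-Z][a-z]?")
_COUNT_RE = re.compile(r"[0-9]+")


def _parse_charge(tail: str, where: str) -> int:
    tail = tail.strip()
    if not tail:
        return 1
    m = re.fullmatch(r"([0-9]*)(\++)", tail)
    if m is None:
        raise FormulaError(f"malformed charge suffix {tail!r} {where}")
    digits, pluses = m.group(1), m.group(2)
    if digits:
        if len(pluses) != 1:
            raise FormulaError(f"malformed charge suffix {tail!r} {where}")
        z = int(digits)
        if z < 1:
            raise FormulaError(f"charge must be >= 1 {where}")
        return z
    return len(pluses)


def _parse_body(text: str, pos: int, stop: str | None,
                counts: dict[str, int], groups: list[tuple[str, int]],
                mult: int, top: bool) -> int:
    saw_any = False
    n = len(text)
    while pos < n:
        ch = text[pos]
        if ch.isspace():
            pos += 1
            continue
        if stop is not None and ch == stop:
            if not saw_any:
                raise FormulaError(f"empty group at position {pos}")
            return pos
        if ch == "(":
            start = pos + 1
            depth = 1
            i = start
            while i < n and depth:
                if text[i] == "(":
                    depth += 1
                elif text[i] == ")":
                    depth -= 1
                i += 1
            if depth:
                raise FormulaError(f"unbalanced '(' at position {pos}")
            inner = text[start:i - 1]
            cm = _COUNT_RE.match(text, i)
            gcount = int(cm.group()) if cm else 1
            if gcount < 1:
                raise FormulaError(f"zero count at position {i}")
            pos_after = cm.end() if cm else i
            if top:
                groups.append((inner, gcount))
            _parse_body(inner, 0, None, counts, [], mult * gcount, False)
            pos = pos_after
            saw_any = True
            continue
        em = _ELEMENT_RE.match(text, pos)
        if em is None:
            raise FormulaError(f"unexpected character {ch!r} at position {pos}")
        sym = em.group()
        cm = _COUNT_RE.match(text, em.end())
        count = int(cm.group()) if cm else 1
        if count < 1:
            raise FormulaError(f"zero count at position {em.end()}")
        pos = cm.end() if cm else em.end()
        counts[sym] = counts.get(sym, 0) + count * mult
        if top:
            groups.append((sym, count))
        saw_any = True
    if stop is not None:
        raise FormulaError(f"expected {stop!r} before end of input")
    if not saw_any:
        raise FormulaError("empty formula")
    return pos


def parse_formula(text: str, *, validate: bool = True) -> Formula:
    """Parse a formula string such as ``"(C60)3Na12"`` or ``"C40 2+"``.

    Element symbols are capital + optional lowercase letter; integer counts
    follow an element or a parenthesised group; the charge is a trailing
    ``z+`` (``"[(C60)3Na12H2O]+"``, ``"C40 2+"``, ``"C40++"``), default 1.
    With ``validate`` every symbol must be in the element registry.
    """
    label = text.strip()
    if not label:
        raise FormulaError("empty formula")
    s = label
    charge = 1
    if s.startswith("["):
        close = s.rfind("]")
        if close < 0:
            raise FormulaError("unbalanced '[' in formula")
        charge = _parse_charge(s[close + 1:], f"in {label!r}")
        s = s[1:close]
    else:
        m = re.fullmatch(r"(.*?)\s+([0-9]+)\+", s, re.S)
        if m:
            s = m.group(1)
            charge = _parse_charge(m.group(2) + "+", f"in {label!r}")
        else:
            m = re.fullmatch(r"(.*?)(\++)", s, re.S)
            if m and m.group(1).strip():
                s = m.group(1)
                charge = len(m.group(2))
    counts: dict[str, int] = {}
    groups: list[tuple[str, int]] = []
    _parse_body(s, 0, None, counts, groups, 1, True)
    if validate:
        for sym in counts:
            get_element(sym)  # raises FormulaError for unknown symbols
    return Formula(tuple(counts.items()), charge=charge, label=label,
                   groups=tuple(groups))


# ---------------------------------------------------------------------------
# Pattern algebra
# ---------------------------------------------------------------------------

def element_pattern(e: ElementRecord) -> IsotopePattern:
    """The stick pattern of a bare element: its (mass, abundance) pairs."""
    return IsotopePattern(e.masses.copy(), e.abundances.copy())


def prune_low(p: IsotopePattern, eps_a: float) -> IsotopePattern:
    """Drop sticks with abundance < eps_a.  No renormalisation."""
    if not (0.0 <= eps_a < 1.0):
        raise ValueError("eps_a must be in [0, 1)")
    if eps_a == 0.0 or len(p) == 0:
        return p
    keep = p.abundances >= eps_a
    return IsotopePattern(p.masses[keep], p.abundances[keep])


def merge_close(p: IsotopePattern, eps_m: float) -> IsotopePattern:
    """Merge maximal runs of sticks whose successive gaps are < eps_m.

    Each run becomes one stick with the summed abundance at the
    abundance-weighted centre of mass; total abundance and the first mass
    moment are conserved exactly.
    """
    if eps_m < 0.0:
        raise ValueError("eps_m must be >= 0")
    if eps_m == 0.0 or len(p) < 2:
        return p
    # run boundaries where the gap to the previous stick is >= eps_m
    breaks = np.flatnonzero(np.diff(p.masses) >= eps_m) + 1
    if breaks.size == len(p) - 1:
        return p
    groups = np.concatenate(([0], breaks, [len(p)]))
    a_out = np.add.reduceat(p.abundances, groups[:-1])
    am_out = np.add.reduceat(p.abundances * p.masses, groups[:-1])
    return IsotopePattern(am_out / a_out, a_out)


def _apply(p: IsotopePattern, cfg: PruneConfig) -> IsotopePattern:
    return prune_low(merge_close(p, cfg.eps_m), cfg.eps_a)


def convolve(p: IsotopePattern, q: IsotopePattern,
             cfg: PruneConfig = PruneConfig()) -> IsotopePattern:
    """Convolution of two stick patterns: all pairwise mass sums with
    multiplied abundances; coinciding masses (within the floating-point
    collision floor) combine; then merge/prune."""
    if len(p) == 0 or len(q) == 0:
        raise ValueError("cannot convolve an empty pattern")
    m = (p.masses[:, None] + q.masses[None, :]).ravel()
    a = (p.abundances[:, None] * q.abundances[None, :]).ravel()
    mu, inv = np.unique(m, return_inverse=True)
    au = np.zeros_like(mu)
    np.add.at(au, inv, a)
    keep = au > 0  # products can underflow to exactly zero for huge molecules
    out = merge_close(IsotopePattern(mu[keep], au[keep]), FP_MERGE_EPS_DA)
    return _apply(out, cfg)


def pattern_power(p: IsotopePattern, n: int,
                  cfg: PruneConfig = PruneConfig()) -> IsotopePattern:
    """n-fold self-convolution by binary exponentiation.

    The merge/prune approximations run after every convolution step, keeping
    the stick count bounded for large homonuclear clusters.
    """
    if n < 1:
        raise ValueError("power must be >= 1")
    result: IsotopePattern | None = None
    base = p
    while n:
        if n & 1:
            result = base if result is None else convolve(result, base, cfg)
        n >>= 1
        if n:
            base = convolve(base, base, cfg)
    assert result is not None
    return result


def species_pattern(f: Formula, cfg: PruneConfig = PruneConfig(), *,
                    electron_mass_correction: bool = False) -> IsotopePattern:
    """Isotopic pattern of a molecule/cluster, on the m/z axis for charge z.

    Convolves the element patterns (powers via binary exponentiation) and
    divides stick masses by z.  With ``electron_mass_correction`` the mass of
    z electrons is subtracted before the division (off by default).
    """
    pattern: IsotopePattern | None = None
    for sym, count in f.components:
        part = pattern_power(element_pattern(get_element(sym)), count, cfg)
        pattern = part if pattern is None else convolve(pattern, part, cfg)
    assert pattern is not None
    masses = pattern.masses
    if electron_mass_correction:
        masses = masses - f.charge * ELECTRON_MASS_DA
    if f.charge != 1:
        masses = masses / f.charge
    return IsotopePattern(masses, pattern.abundances)


# ---------------------------------------------------------------------------
# Series enumeration
# ---------------------------------------------------------------------------

def expand_series(units: Sequence[tuple[str, int, int]], charge: int = 1) -> list[Formula]:
    """Enumerate a cluster series over a grid of per-unit counts.

    ``units`` is a list of (unit, lo, hi) where unit is an element symbol or
    a parenthesisable sub-formula; every combination with counts in
    [lo, hi] per unit is produced (count 0 omits the unit; the all-zero
    combination is skipped).  E.g. ``[("C60", 1, 10), ("Na", 0, 40),
    ("H2O", 0, 1)]`` yields 10*41*2 = 820 formulas.
    """
    combos: list[list[tuple[str, int]]] = [[]]
    for unit, lo, hi in units:
        if lo < 0 or hi < lo:
            raise ValueError(f"bad count range for {unit!r}")
        combos = [c + [(unit, n)] for c in combos for n in range(lo, hi + 1)]
    out = []
    for combo in combos:
        parts = [(u, n) for u, n in combo if n > 0]
        if not parts:
            continue
        text = "".join(
            (u if len(_ELEMENT_RE.findall(u)) <= 1 and not _COUNT_RE.search(u)
             else f"({u})") + (str(n) if n > 1 else "")
            for u, n in parts)
        suffix = "+" if charge == 1 else f" {charge}+"
        out.append(parse_formula(f"[{text}]{suffix}" if charge == 1 else text + suffix))
    return out
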