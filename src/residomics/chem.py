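"""Small-molecule mass arithmetic for positive-mode LC-MS annotation.

Monoisotopic masses, adduct m/z conventions, isotopologue-envelope
simulation, and exhaustive CHNO formula prediction from accurate mass.
The element table (monoisotopic masses and natural isotope abundances)
is bundled as a versioned CSV under :mod:`residomics.data`.

The default hydrogen convention for "[M+H]+" adds the mass of a hydrogen
*atom* (1.00783 Da) with no electron correction; this is the convention
under which leucine enkephalin (C28H37N5O7) gives the familiar lockmass
556.2771.  An electron-corrected proton convention is available via
``hydrogen_convention="proton"``.
"""

from __future__ import annotations

import csv
import importlib.resources
import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "C13_C12_DELTA",
    "ElementFormula",
    "AdductSpec",
    "IsotopePattern",
    "FormulaCandidate",
    "UnsupportedElementError",
    "parse_adduct",
    "monoisotopic_mass",
    "adduct_mz",
    "simulate_isotope_pattern",
    "isotope_score",
    "predict_formulas",
]

ELECTRON_MASS = 0.000549  # Da
#: Mass difference between 13C and 12C — the spacing of isotopologue ladders.
C13_C12_DELTA = 1.003355


class UnsupportedElementError(ValueError):
    """An element symbol absent from the bundled element table."""

    def __init__(self, symbol: str):
        super().__init__(f"unsupported element symbol: {symbol!r}")
        self.symbol = symbol


@lru_cache(maxsize=1)
def element_table() -> dict[str, list[tuple[int, float, float]]]:
    """Load the bundled element table.

    Returns a mapping ``symbol -> [(nucleon shift, mass Da, abundance), ...]``
    sorted by shift; the shift-0 entry is the monoisotopic (most abundant
    light) isotope.
    """
    table: dict[str, list[tuple[int, float, float]]] = {}
    ref = importlib.resources.files("residomics.data") / "elements.csv"
    with ref.open() as fh:
        rows = [r for r in fh if not r.startswith("#")]
    for rec in csv.DictReader(rows):
        table.setdefault(rec["element"], []).append(
            (int(rec["shift"]), float(rec["mass"]), float(rec["abundance"]))
        )
    for isotopes in table.values():
        isotopes.sort()
    return table


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementFormula:
    """An elemental composition with non-negative integer counts.

    ``ElementFormula.parse("C10H14N2")`` parses a Hill-style string;
    the empty formula (mass 0) is permitted and represents a bare adduct.
    """

    counts: Mapping[str, int]

    def __post_init__(self):
        table = element_table()
        clean = {}
        for sym, n in self.counts.items():
            if sym not in table:
                raise UnsupportedElementError(sym)
            if n < 0 or n != int(n):
                raise ValueError(f"count for {sym} must be a non-negative integer")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementFormula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda s: (s != "C", s != "H", s))
        return "".join(f"{s}{self.counts[s] if self.counts[s] != 1 else ''}" for s in order)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(formula: ElementFormula | str | Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of count x lightest-isotope mass."""
    if isinstance(formula, str):
        formula = ElementFormula.parse(formula)
    elif not isinstance(formula, ElementFormula):
        formula = ElementFormula(formula)
    table = element_table()
    return float(sum(n * table[s][0][1] for s, n in formula.counts.items()))


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: name, total mass delta (Da), and charge.

    ``hydrogen_convention`` records whether H-containing deltas were built
    from the hydrogen atom mass (``"atom"``, default — no electron
    correction) or the proton mass (``"proton"``).
    """

    name: str
    delta: float
    charge: int
    hydrogen_convention: str = "atom"

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("adduct charge must be >= 1")
        if not np.isfinite(self.delta):
            raise ValueError("adduct delta must be finite")


_ADDUCT_RE = re.compile(r"^\[M((?:[+-]\d*[A-Za-z][A-Za-z0-9]*)*)\](\d*)\+$")
_TERM_RE = re.compile(r"([+-])(\d*)([A-Za-z][A-Za-z0-9]*)")


def parse_adduct(name: str, hydrogen_convention: str = "atom") -> AdductSpec:
    """Parse a positive-mode adduct name like ``[M+H]+`` or ``[M+2Na]+``.

    Terms are element-formula fragments with optional stoichiometry; the
    trailing digit before ``+`` is the charge.  Under the ``"proton"``
    convention the electron mass times charge is subtracted from the delta.
    """
    m = _ADDUCT_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse adduct {name!r}")
    if hydrogen_convention not in ("atom", "proton"):
        raise ValueError("hydrogen_convention must be 'atom' or 'proton'")
    delta = 0.0
    for sign, count, species in _TERM_RE.findall(m.group(1)):
        k = int(count or 1) * (1 if sign == "+" else -1)
        delta += k * monoisotopic_mass(ElementFormula.parse(species))
    charge = int(m.group(2) or 1)
    if hydrogen_convention == "proton":
        delta -= charge * ELECTRON_MASS
    return AdductSpec(name=name, delta=delta, charge=charge,
                      hydrogen_convention=hydrogen_convention)


def adduct_mz(formula: ElementFormula | str, adduct: AdductSpec | str) -> float:
    """m/z of the adduct ion: (monoisotopic mass + delta) / charge."""
    if isinstance(adduct, str):
        adduct = parse_adduct(adduct)
    return (monoisotopic_mass(formula) + adduct.delta) / adduct.charge


@dataclass(frozen=True)
class IsotopePattern:
    """An isotopologue envelope relative to the monoisotopic (A+0) peak.

    ``offsets`` are m/z offsets in Da (strictly increasing, first = 0),
    ``abundances`` are fractions of the base peak (base = 1).
    ``raw_probabilities``, when present, are the un-normalized isotopologue
    probabilities (summing to <= 1 over the simulated peaks).
    """

    offsets: tuple[float, ...]
    abundances: tuple[float, ...]
    raw_probabilities: tuple[float, ...] | None = None

    def __post_init__(self):
        if not self.abundances:
            raise ValueError("pattern must have at least one peak")
        if abs(max(self.abundances) - 1.0) > 1e-12:
            raise ValueError("base peak abundance must be 1")
        if any(b - a <= 0 for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")


def _element_envelope(symbol: str, n_atoms: int, n_peaks: int) -> np.ndarray:
    """Probability vector over nucleon shifts 0..n_peaks-1 for n identical atoms."""
    isotopes = element_table()[symbol]
    base = np.zeros(n_peaks)
    for shift, _mass, abundance in isotopes:
        if shift < n_peaks:
            base[shift] += abundance
    # exponentiation by repeated convolution, truncated to n_peaks
    out = np.zeros(n_peaks)
    out[0] = 1.0
    power = base
    k = n_atoms
    while k:
        if k & 1:
            out = np.convolve(out, power)[:n_peaks]
        k >>= 1
        if k:
            power = np.convolve(power, power)[:n_peaks]
    return out


def simulate_isotope_pattern(
    formula: ElementFormula | str,
    adduct: AdductSpec | str | None = None,
    n_peaks: int = 3,
) -> IsotopePattern:
    """Simulate the A+0 .. A+(n_peaks-1) isotopologue envelope.

    Per-element isotope distributions are convolved (polynomial expansion)
    and truncated at ``n_peaks`` nucleon shifts.  Peak spacing is the
    13C-12C mass difference divided by the adduct charge — adequate for the
    CHNO chemistry this package targets.  If an adduct is given its atoms
    are included in the convolution.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if isinstance(formula, str):
        formula = ElementFormula.parse(formula)
    charge = 1
    counts = dict(formula.counts)
    if adduct is not None:
        if isinstance(adduct, str):
            adduct = parse_adduct(adduct)
        charge = adduct.charge
        for sign, count, species in _TERM_RE.findall(_ADDUCT_RE.match(adduct.name).group(1)):
            k = int(count or 1) * (1 if sign == "+" else -1)
            for sym, n in ElementFormula.parse(species).counts.items():
                counts[sym] = counts.get(sym, 0) + k * n
    if not any(n > 0 for n in counts.values()):
        # empty/degenerate formula: a single monoisotopic peak
        return IsotopePattern(offsets=(0.0,), abundances=(1.0,),
                              raw_probabilities=(1.0,))
    env = np.zeros(n_peaks)
    env[0] = 1.0
    for sym, n in counts.items():
        if n > 0:
            env = np.convolve(env, _element_envelope(sym, n, n_peaks))[:n_peaks]
    base = env[0] if env[0] > 0 else env.max()
    rel = env / base
    offsets = tuple(i * C13_C12_DELTA / charge for i in range(n_peaks))
    return IsotopePattern(offsets=offsets, abundances=tuple(rel / rel.max()),
                          raw_probabilities=tuple(env))


def isotope_score(observed: IsotopePattern, theoretical: IsotopePattern) -> float:
    """Envelope agreement in percent: 100 * (1 - sum|obs-theo| / sum theo).

    Peaks are matched by isotopologue index over the shorter envelope; both
    patterns are base-peak normalized.  Clipped to [0, 100]; monotone in
    agreement and 100 only for a perfect match.
    """
    k = min(len(observed.abundances), len(theoretical.abundances))
    obs = np.asarray(observed.abundances[:k])
    theo = np.asarray(theoretical.abundances[:k])
    score = 100.0 * (1.0 - np.abs(obs - theo).sum() / theo.sum())
    return float(np.clip(score, 0.0, 100.0))


@dataclass(frozen=True)
class FormulaCandidate:
    formula: ElementFormula
    mz: float
    ppm_error: float
    isotope_score_pct: float | None = None

    def __str__(self) -> str:
        s = f"{self.formula}\t{self.mz:.4f}\t{self.ppm_error:+.3f} ppm"
        if self.isotope_score_pct is not None:
            s += f"\t{self.isotope_score_pct:.1f}%"
        return s


DEFAULT_RANGES: dict[str, tuple[int, int]] = {
    "C": (0, 50), "H": (0, 100), "N": (0, 5), "O": (0, 40),
}


def _rdbe(counts: Mapping[str, int]) -> float:
    return counts.get("C", 0) - counts.get("H", 0) / 2 + counts.get("N", 0) / 2 + 1


def predict_formulas(
    query_mz: float,
    tolerance_ppm: float = 3.0,
    ranges: Mapping[str, tuple[int, int]] | None = None,
    adduct: AdductSpec | str = "[M+H]+",
    observed_pattern: IsotopePattern | None = None,
    min_isotope_score: float = 95.0,
    tolerance_mz: float = 0.0,
    nitrogen_rule: bool = False,
    min_rdbe: float | None = None,
) -> list[FormulaCandidate]:
    """Exhaustive formula prediction within a mass window.

    Enumerates the integer lattice of element counts within ``ranges``,
    keeping every formula whose adduct m/z lies within
    ``max(tolerance_mz, tolerance_ppm * query_mz / 1e6)`` of the query.
    Candidates are sorted by absolute mass error (ppm), ties broken
    lexicographically by (C, H, N, O, ...) counts.  When an observed
    isotope pattern is supplied, candidates scoring below
    ``min_isotope_score`` percent are dropped.

    The search solves the hydrogen count analytically from the mass
    residual of each non-hydrogen combination, so cost scales with the
    product of the non-H range widths, not the full lattice.
    """
    if tolerance_ppm <= 0 and tolerance_mz <= 0:
        raise ValueError("tolerance must be positive")
    if not ranges:
        if ranges is not None:
            raise ValueError("element ranges must be non-empty")
        ranges = DEFAULT_RANGES
    if isinstance(adduct, str):
        adduct = parse_adduct(adduct)
    table = element_table()
    for sym in ranges:
        if sym not in table:
            raise UnsupportedElementError(sym)

    window = max(tolerance_mz, tolerance_ppm * query_mz / 1e6)  # in m/z units
    target = query_mz * adduct.charge - adduct.delta            # neutral mass
    window_da = window * adduct.charge
    m_h = table["H"][0][1]

    others = sorted(s for s in ranges if s != "H")
    h_lo, h_hi = ranges.get("H", (0, 0))
    axes = [np.arange(ranges[s][0], ranges[s][1] + 1) for s in others]
    if any(a.size == 0 for a in axes) or h_lo > h_hi:
        raise ValueError("element ranges must be non-empty")
    grids = np.meshgrid(*axes, indexing="ij") if axes else []
    partial = np.zeros(grids[0].shape if grids else ())
    for sym, g in zip(others, grids):
        partial = partial + g * table[sym][0][1]
    resid = target - partial

    candidates: list[tuple[float, tuple[int, ...], FormulaCandidate]] = []
    h_center = np.rint(resid / m_h).astype(int) if others else None

    def consider(counts_other: tuple[int, ...], h: int):
        if not (h_lo <= h <= h_hi):
            return
        counts = dict(zip(others, counts_other))
        counts["H"] = h
        mass = sum(n * table[s][0][1] for s, n in counts.items())
        mz = (mass + adduct.delta) / adduct.charge
        ppm = (mz - query_mz) / query_mz * 1e6
        if abs(mz - query_mz) > window + 1e-12:
            return
        if nitrogen_rule and (counts.get("N", 0) % 2) != (round(mass) % 2):
            return
        if min_rdbe is not None and _rdbe(counts) < min_rdbe:
            return
        formula = ElementFormula({s: n for s, n in counts.items() if n})
        score = None
        if observed_pattern is not None:
            theo = simulate_isotope_pattern(formula, adduct,
                                            n_peaks=len(observed_pattern.abundances))
            score = isotope_score(observed_pattern, theo)
            if score < min_isotope_score:
                return
        key = tuple(counts.get(s, 0) for s in ("C", "H", "N", "O")) + tuple(
            counts.get(s, 0) for s in sorted(counts) if s not in ("C", "H", "N", "O"))
        candidates.append((abs(ppm), key, FormulaCandidate(formula, mz, ppm, score)))

    if others:
        it = np.nditer([*grids, resid, h_center], flags=["multi_index"])
        for *vals, r, hc in it:
            r = float(r)
            if r < -window_da - m_h:
                continue
            hc = int(hc)
            for h in (hc - 1, hc, hc + 1):
                if h >= 0 and abs(r - h * m_h) <= window_da + 1e-12:
                    consider(tuple(int(v) for v in vals), h)
    else:
        hc = int(np.rint(target / m_h))
        for h in (hc - 1, hc, hc + 1):
            if h >= 0 and abs(target - h * m_h) <= window_da + 1e-12:
                consider((), h)

    candidates.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in candidates]
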