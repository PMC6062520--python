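"""Accurate-mass identification support.

Elemental-formula monoisotopic masses, adduct m/z arithmetic with explicit
electron-mass bookkeeping, ppm matching against an offline compound table
(≤3 ppm rule, odd-acyl-carbon exclusion for lipids), isotope-pattern
prediction by exact multinomial expansion over natural abundances, and
CID neutral-loss fragment assignment at ~1 mDa.

All annotation is offline against user-supplied (or the bundled) compound
tables; no web service is queried.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

#: Most-abundant-isotope atomic masses (Da), CODATA/IUPAC values.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "K": 38.96370668,
    "Fe": 55.9349375,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Br": 78.9183371,
}

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = 1.007276466879  # Da

#: Natural isotopes per element: (mass Da, abundance, nucleon offset from
#: the most abundant isotope). Offsets may be negative (e.g. 54Fe).
ISOTOPES = {
    "C": [(12.0, 0.9893, 0), (13.0033548378, 0.0107, 1)],
    "H": [(1.00782503207, 0.999885, 0), (2.0141017778, 0.000115, 1)],
    "N": [(14.0030740048, 0.99636, 0), (15.0001088982, 0.00364, 1)],
    "O": [(15.9949146196, 0.99757, 0), (16.9991317, 0.00038, 1), (17.999161, 0.00205, 2)],
    "P": [(30.97376163, 1.0, 0)],
    "S": [
        (31.97207100, 0.9499, 0),
        (32.97145876, 0.0075, 1),
        (33.96786690, 0.0425, 2),
        (35.96708076, 0.0001, 4),
    ],
    "K": [(38.96370668, 0.932581, 0), (39.96399848, 0.000117, 1), (40.96182576, 0.067302, 2)],
    "Fe": [
        (53.9396105, 0.05845, -2),
        (55.9349375, 0.91754, 0),
        (56.9353940, 0.02119, 1),
        (57.9332756, 0.00282, 2),
    ],
    "Cl": [(34.96885268, 0.7576, 0), (36.96590259, 0.2424, 2)],
    "F": [(18.99840322, 1.0, 0)],
    "Na": [(22.9897692809, 1.0, 0)],
    "Br": [(78.9183371, 0.5069, 0), (80.9162906, 0.4931, 2)],
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element → count map, hashable and printable as a Hill-ish string."""

    counts: tuple  # sorted tuple of (element, count)

    @classmethod
    def parse(cls, formula: str) -> "ElementalFormula":
        """Parse e.g. ``C34H32FeN4O4``; unknown elements are rejected."""
        if not formula or not formula.strip():
            raise DataError("empty formula")
        pos = 0
        counts: dict[str, int] = {}
        text = formula.strip()
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if not m or not m.group(1):
                raise DataError(f"cannot parse formula {formula!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            if el not in MONOISOTOPIC_MASS:
                raise DataError(f"unsupported element {el!r} in formula {formula!r}")
            n = int(num) if num else 1
            if n <= 0:
                raise DataError(f"non-positive count for {el!r} in {formula!r}")
            counts[el] = counts.get(el, 0) + n
            pos = m.end()
        return cls(tuple(sorted(counts.items())))

    def as_dict(self) -> dict:
        return dict(self.counts)

    def __str__(self) -> str:
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(n for _el, n in self.counts)


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Sum of most-abundant-isotope atomic masses (Da)."""
    if isinstance(f, str):
        f = ElementalFormula.parse(f)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts)


@dataclass(frozen=True)
class AdductSpec:
    """Named ionization: m/z = (neutral + mass_delta) / |charge|.

    ``mass_delta`` carries the electron-mass bookkeeping explicitly: a
    proton adds 1.007276 Da, K⁺ adds 38.963707 − mₑ, a radical cation
    subtracts one electron mass.
    """

    name: str
    mass_delta: float
    charge: int = 1


COMMON_ADDUCTS = {
    "[M+H]+": AdductSpec("[M+H]+", PROTON_MASS, +1),
    "[M+Na]+": AdductSpec("[M+Na]+", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
    "[M+K]+": AdductSpec("[M+K]+", MONOISOTOPIC_MASS["K"] - ELECTRON_MASS, +1),
    "[M]+.": AdductSpec("[M]+.", -ELECTRON_MASS, +1),
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
}


def adduct_mz(neutral: float, adduct: AdductSpec) -> float:
    """m/z of an adducted species from the neutral monoisotopic mass."""
    if neutral <= 0:
        raise DataError("neutral mass must be positive")
    return (neutral + adduct.mass_delta) / abs(adduct.charge)


def ppm_error(measured: float, theoretical: float) -> float:
    """|measured − theoretical| / theoretical × 1e6 (denominator: theoretical)."""
    if theoretical <= 0:
        raise DataError("theoretical mass must be positive")
    return abs(measured - theoretical) / theoretical * 1e6


@dataclass
class CompoundRecord:
    """A candidate identification: name, formula, class, optional acyl carbons."""

    name: str
    formula: ElementalFormula
    compound_class: str = ""
    acyl_carbons: int | None = None

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass
class Hit:
    compound: CompoundRecord
    adduct: AdductSpec
    theoretical_mz: float
    ppm: float


def search_compounds(
    measured: float,
    table,
    adducts=None,
    max_ppm: float = 3.0,
    exclude_odd_acyl: bool = True,
) -> list:
    """Rank (compound, adduct) pairs within ``max_ppm`` of a measured m/z.

    Hits are sorted ascending by ppm error (stable in compound/adduct name
    for ties, so results do not depend on table order). Lipid records whose
    ``acyl_carbons`` is odd are removed when the odd-carbon exclusion rule
    is enabled; records without that metadata are never affected by it.
    """
    if not table:
        raise DataError("empty compound table")
    if adducts is None:
        adducts = [a for n, a in COMMON_ADDUCTS.items() if a.charge > 0]
    hits = []
    for rec in table:
        if exclude_odd_acyl and rec.acyl_carbons is not None and rec.acyl_carbons % 2 == 1:
            continue
        for adduct in adducts:
            theo = adduct_mz(rec.neutral_mass, adduct)
            err = ppm_error(measured, theo)
            if err <= max_ppm:
                hits.append(Hit(rec, adduct, theo, err))
    hits.sort(key=lambda h: (h.ppm, h.compound.name, h.adduct.name))
    return hits


@dataclass
class IsotopePattern:
    """Nucleon-number-aggregated isotope distribution, abundances summing to 1."""

    mz: np.ndarray
    abundance: np.ndarray


def _element_distribution(el: str, n: int, max_offset: int) -> dict:
    """Offset → (probability, probability-weighted mass) for n atoms of el."""
    single = {off: (ab, ab * m) for m, ab, off in ISOTOPES[el]}
    dist = {0: (1.0, 0.0)}
    for _ in range(n):
        new: dict[int, list[float]] = {}
        for o1, (p1, w1) in dist.items():
            m1 = w1 / p1 if p1 > 0 else 0.0
            for o2, (p2, w2) in single.items():
                m2 = w2 / p2 if p2 > 0 else 0.0
                o = o1 + o2
                if o > max_offset:
                    continue
                p = p1 * p2
                if p < 1e-18:
                    continue
                acc = new.setdefault(o, [0.0, 0.0])
                acc[0] += p
                acc[1] += p * (m1 + m2)
        dist = {o: (p, w) for o, (p, w) in new.items()}
    return dist


def isotope_pattern(
    f: ElementalFormula | str, n_peaks: int = 3, adduct: AdductSpec | None = None
) -> IsotopePattern:
    """Exact multinomial isotope distribution aggregated by nucleon number.

    Peaks are the offsets 0 … ``n_peaks``−1 relative to the monoisotopic
    composition (offsets below the monoisotopic peak, e.g. the ⁵⁴Fe
    satellite, are outside the reported M, M+1, … ladder), renormalized to
    sum to 1. Peak m/z values are abundance-weighted mean masses, shifted
    by the adduct delta when one is given.
    """
    if isinstance(f, str):
        f = ElementalFormula.parse(f)
    if n_peaks < 1:
        raise DataError("n_peaks must be >= 1")
    max_offset = n_peaks - 1 + 2  # headroom before truncation
    total = {0: (1.0, 0.0)}
    for el, n in f.counts:
        part = _element_distribution(el, n, max_offset)
        new: dict[int, list[float]] = {}
        for o1, (p1, w1) in total.items():
            m1 = w1 / p1 if p1 > 0 else 0.0
            for o2, (p2, w2) in part.items():
                m2 = w2 / p2 if p2 > 0 else 0.0
                o = o1 + o2
                if o > max_offset:
                    continue
                p = p1 * p2
                if p < 1e-18:
                    continue
                acc = new.setdefault(o, [0.0, 0.0])
                acc[0] += p
                acc[1] += p * (m1 + m2)
        total = {o: (p, w) for o, (p, w) in new.items()}
    delta = adduct.mass_delta / abs(adduct.charge) if adduct else 0.0
    offsets = [o for o in range(n_peaks) if o in total]
    probs = np.array([total[o][0] for o in offsets])
    masses = np.array([total[o][1] / total[o][0] + delta for o in offsets])
    probs = probs / probs.sum()
    return IsotopePattern(masses, probs)


@dataclass
class FragmentAssignment:
    fragment_mz: float
    losses: tuple  # names of the lost neutrals, with multiplicity
    expected_mz: float
    error_mda: float


#: Neutral losses seen in positive-mode CID of the study's marker classes:
#: carboxymethyl side chains of porphyrins and the trimethylamine /
#: head-group losses of phosphatidylcholines, plus water.
DEFAULT_NEUTRAL_LOSSES = (
    ("CH2COOH side chain", "C2H3O2"),
    ("trimethylamine", "C3H9N"),
    ("water", "H2O"),
)


def match_fragments(
    precursor_mz: float,
    fragment_mzs,
    losses=DEFAULT_NEUTRAL_LOSSES,
    tol_mda: float = 1.5,
    depth: int = 2,
) -> list:
    """Assign fragments as combinations of neutral losses from the precursor.

    Every multiset of up to ``depth`` losses is tried; a fragment is
    assigned when the observed m/z lies within ``tol_mda`` mDa of
    ``precursor − Σ loss masses``. Repeated losses (e.g. two CH2COOH side
    chains) are covered by combinations with replacement.
    """
    loss_masses = [(name, monoisotopic_mass(formula)) for name, formula in losses]
    assignments = []
    for size in range(1, depth + 1):
        for combo in itertools.combinations_with_replacement(loss_masses, size):
            expected = precursor_mz - sum(m for _n, m in combo)
            for frag in fragment_mzs:
                err_mda = (frag - expected) * 1000.0
                if abs(err_mda) <= tol_mda:
                    assignments.append(
                        FragmentAssignment(
                            fragment_mz=float(frag),
                            losses=tuple(n for n, _m in combo),
                            expected_mz=expected,
                            error_mda=float(err_mda),
                        )
                    )
    assignments.sort(key=lambda a: (a.fragment_mz, len(a.losses)))
    return assignments


def load_compound_table(path=None) -> list:
    """Load a compound table CSV (name, formula, class, acyl_carbons).

    Without a path the bundled mini table (study markers and drugs) is used.
    """
    if path is None:
        source = resources.files("wcmaldi").joinpath("data/compounds.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(Path(path))
    required = {"name", "formula"}
    if not required.issubset(df.columns):
        raise DataError(f"compound table needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        acyl = row.get("acyl_carbons")
        acyl = None if pd.isna(acyl) else int(acyl)
        records.append(
            CompoundRecord(
                name=str(row["name"]),
                formula=ElementalFormula.parse(str(row["formula"])),
                compound_class=str(row.get("class", "") or ""),
                acyl_carbons=acyl,
            )
        )
    return records
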