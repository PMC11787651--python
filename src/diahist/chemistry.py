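"""Monoisotopic mass bookkeeping for derivatized histone peptides.

Histone PTM analysis by bottom-up MS works on chemically propionylated
peptides: every free or monomethylated lysine epsilon-amine and every peptide
N-terminus carries a propionyl group (C3H4O, +56.026 Da), which blocks tryptic
cleavage at lysine and improves C18 retention.  This module provides the mass
arithmetic that everything downstream relies on: modification deltas from
elemental formulas, neutral peptide masses, precursor and b/y fragment m/z,
and isotope envelopes computed from the exact elemental composition.

Two mass facts drive the rest of the package: trimethylation (+42.047 Da) and
acetylation (+42.011 Da) are pseudo-isobaric (0.036 Da apart), and positional
isomers (same modification, different lysine) are exactly isobaric and can
only be told apart by fragment ions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "NEUTRON_SPACING",
    "Modification",
    "ModificationRegistry",
    "ModifiedPeptideForm",
    "IsotopeEnvelope",
    "default_registry",
    "modification_delta",
    "apply_propionylation",
    "monoisotopic_mass",
    "composition",
    "precursor_mz",
    "fragment_mz_series",
    "isotope_envelope",
]

#: Mass of a proton (charge carrier), Da.
PROTON_MASS = 1.007276
#: Monoisotopic mass of H2O, Da.
WATER_MASS = _pmass.calculate_mass(formula="H2O")
#: 13C - 12C mass difference, Da; isotopologue spacing is ~ this / charge.
NEUTRON_SPACING = 1.0033548378

N_TERM = "N-term"

PositionKey = Union[int, str]  # 1-based peptide position or "N-term"


@lru_cache(maxsize=256)
def _formula_mass(formula: str) -> float:
    return _pmass.calculate_mass(formula=formula)


@lru_cache(maxsize=256)
def _formula_composition(formula: str) -> Mapping[str, int]:
    return dict(_pmass.Composition(formula=formula))


@dataclass(frozen=True)
class Modification:
    """A named mass shift with its residue targets and elemental formula."""

    name: str
    targets: frozenset
    formula: str
    description: str = ""

    @property
    def delta(self) -> float:
        """Monoisotopic mass shift in Da."""
        return _formula_mass(self.formula)

    @property
    def composition(self) -> Mapping[str, int]:
        return _formula_composition(self.formula)

    def applies_to(self, residue_or_terminus: str) -> bool:
        return residue_or_terminus in self.targets

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class ModificationRegistry:
    """Name -> Modification lookup, loadable from a TSV config.

    The bundled default covers ac, me1, me2, me3, prop, ph and acme (the
    methyl-acetyl "Kacme" mark); users can register additional entries.
    """

    def __init__(self, mods: Iterable[Modification] = ()):
        self._mods: dict[str, Modification] = {}
        for m in mods:
            self.register(m)

    def register(self, mod: Modification) -> None:
        if mod.name in self._mods:
            raise ValueError(f"modification name already registered: {mod.name!r}")
        if abs(mod.delta - _formula_mass(mod.formula)) > 1e-4:
            raise ValueError(f"delta/composition mismatch for {mod.name!r}")
        self._mods[mod.name] = mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            raise KeyError(f"unknown modification: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def __iter__(self):
        return iter(self._mods.values())

    def __len__(self) -> int:
        return len(self._mods)

    def delta(self, name: str) -> float:
        return self[name].delta

    @classmethod
    def from_table(cls, path) -> "ModificationRegistry":
        reg = cls()
        with open(path) as fh:
            header = None
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    continue
                row = dict(zip(header, fields))
                targets = frozenset(t.strip() for t in row["targets"].split(","))
                reg.register(
                    Modification(
                        name=row["name"],
                        targets=targets,
                        formula=row["formula"],
                        description=row.get("description", ""),
                    )
                )
        return reg


@lru_cache(maxsize=1)
def default_registry() -> ModificationRegistry:
    """Registry loaded from the bundled modification table."""
    ref = resources.files("diahist.data").joinpath("modifications.tsv")
    with resources.as_file(ref) as path:
        return ModificationRegistry.from_table(path)


def modification_delta(name: str, registry: ModificationRegistry | None = None) -> float:
    """Monoisotopic mass shift of a registered modification, in Da."""
    registry = registry or default_registry()
    return registry.delta(name)


def _normalize_placements(
    placements: Mapping[PositionKey, object],
) -> dict[PositionKey, tuple[Modification, ...]]:
    out: dict[PositionKey, tuple[Modification, ...]] = {}
    for pos, mods in placements.items():
        if isinstance(mods, Modification):
            mods = (mods,)
        else:
            mods = tuple(mods)
        out[pos] = tuple(sorted(mods, key=lambda m: m.name))
    return out


@dataclass
class ModifiedPeptideForm:
    """One derivatized histone peptide with an exact PTM placement.

    ``span`` is 1-based inclusive in protein coordinates, numbered after
    initiator-Met removal (the histone community convention, so that e.g.
    "H4K8ac" means acetyl on the lysine at protein position 8).  Placement
    keys are 1-based peptide positions or ``"N-term"``; values are tuples of
    modifications so that a monomethyl-lysine can also carry its propionyl.
    """

    protein: str
    span: tuple[int, int]
    sequence: str
    placements: Mapping[PositionKey, object] = field(default_factory=dict)
    charges: tuple[int, ...] = (2, 3, 4)

    def __post_init__(self) -> None:
        self.placements = _normalize_placements(self.placements)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.sequence)
        if self.span[1] - self.span[0] + 1 != n:
            raise ValueError(
                f"span {self.span} inconsistent with sequence length {n}"
            )
        for res in self.sequence:
            if res not in _pmass.std_aa_mass:
                raise ValueError(f"unknown residue code: {res!r}")
        for pos, mods in self.placements.items():
            if pos == N_TERM:
                site = N_TERM
            else:
                if not (1 <= int(pos) <= n):
                    raise ValueError(f"placement position {pos} outside 1..{n}")
                site = self.sequence[int(pos) - 1]
            for m in mods:
                if not m.applies_to(site):
                    raise ValueError(
                        f"{m.name} does not target {site!r} (position {pos})"
                    )
            non_deriv = [m for m in mods if m.name != "prop"]
            if len(non_deriv) > 1:
                raise ValueError(
                    f"more than one non-derivatization PTM at position {pos}"
                )

    # -- helpers ---------------------------------------------------------
    def mods_at(self, pos: PositionKey) -> tuple[Modification, ...]:
        return self.placements.get(pos, ())

    def protein_position(self, peptide_pos: int) -> int:
        return self.span[0] + peptide_pos - 1

    @property
    def is_derivatized(self) -> bool:
        return any(m.name == "prop" for mods in self.placements.values() for m in mods)

    @property
    def label(self) -> str:
        """Human-readable form id, e.g. ``"H4 4-17 K8ac"`` (prop omitted)."""
        parts = []
        for pos in sorted((p for p in self.placements if p != N_TERM), key=int):
            for m in self.mods_at(pos):
                if m.name == "prop":
                    continue
                res = self.sequence[int(pos) - 1]
                parts.append(f"{res}{self.protein_position(int(pos))}{m.name}")
        for m in self.mods_at(N_TERM):
            if m.name != "prop":
                parts.append(f"Nterm-{m.name}")
        mods = "".join(parts) if parts else "unmod"
        return f"{self.protein} {self.span[0]}-{self.span[1]} {mods}"

    def with_placements(
        self, placements: Mapping[PositionKey, object]
    ) -> "ModifiedPeptideForm":
        return ModifiedPeptideForm(
            protein=self.protein,
            span=self.span,
            sequence=self.sequence,
            placements=placements,
            charges=self.charges,
        )


def apply_propionylation(
    form: ModifiedPeptideForm, registry: ModificationRegistry | None = None
) -> ModifiedPeptideForm:
    """Derivatize a form: propionyl on the N-terminus and on every lysine
    that is unmodified or carries only monomethyl.

    Acetylated, dimethylated, trimethylated and Kacme lysines keep their
    epsilon-amine blocked and are left untouched.  Raises on input that is
    already derivatized.
    """
    registry = registry or default_registry()
    if form.is_derivatized:
        raise ValueError("form is already derivatized")
    prop = registry["prop"]
    new: dict[PositionKey, tuple[Modification, ...]] = {
        pos: mods for pos, mods in form.placements.items()
    }
    new[N_TERM] = form.mods_at(N_TERM) + (prop,)
    for i, res in enumerate(form.sequence, start=1):
        if res != "K":
            continue
        mods = form.mods_at(i)
        names = {m.name for m in mods}
        if not names or names == {"me1"}:
            new[i] = mods + (prop,)
    return form.with_placements(new)


def monoisotopic_mass(form: ModifiedPeptideForm) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    m = WATER_MASS
    for res in form.sequence:
        m += _pmass.std_aa_mass[res]
    for mods in form.placements.values():
        for mod in mods:
            m += mod.delta
    return m


def composition(form: ModifiedPeptideForm) -> dict[str, int]:
    """Elemental composition of the neutral form."""
    comp: Counter = Counter(_pmass.Composition(formula="H2O"))
    for res in form.sequence:
        comp.update(_pmass.std_aa_comp[res])
    for mods in form.placements.values():
        for mod in mods:
            comp.update(mod.composition)
    return {el: n for el, n in comp.items() if n}


def precursor_mz(mass: float, charge: int) -> float:
    """m/z of a protonated species: (M + z * proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def fragment_mz_series(
    form: ModifiedPeptideForm,
    ion_types: Sequence[str] = ("b", "y"),
    product_charge: int = 1,
) -> list[tuple[str, float]]:
    """All b_i / y_i fragment m/z values with placed modifications included.

    b ions carry the N-terminal modifications; y ions carry the C-terminal
    water, and the full-length y ion additionally carries the N-terminal
    modifications so that y_N coincides with the singly charged precursor.
    """
    if product_charge < 1:
        raise ValueError("product_charge must be >= 1")
    n = len(form.sequence)
    res_mass = [
        _pmass.std_aa_mass[r] + sum(m.delta for m in form.mods_at(i))
        for i, r in enumerate(form.sequence, start=1)
    ]
    nterm = sum(m.delta for m in form.mods_at(N_TERM))
    prefix = np.cumsum(res_mass)
    out: list[tuple[str, float]] = []
    z = product_charge
    if "b" in ion_types:
        for i in range(1, n):
            neutral = prefix[i - 1] + nterm
            out.append((f"b{i}", (neutral + z * PROTON_MASS) / z))
    if "y" in ion_types:
        total = prefix[-1]
        for i in range(1, n + 1):
            neutral = total - (prefix[n - i - 1] if i < n else 0.0) + WATER_MASS
            if i == n:
                neutral += nterm
            out.append((f"y{i}", (neutral + z * PROTON_MASS) / z))
    return out


@dataclass
class IsotopeEnvelope:
    """First-n isotopologue peaks of a charged form.

    Intensities are normalized so the most intense peak is 1; m/z values are
    spaced by ~1.00336/charge (aggregated-isotopologue approximation).
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative isotope intensity")

    def __len__(self) -> int:
        return len(self.mz)


def _isotope_offsets(element: str) -> tuple[np.ndarray, float]:
    """(abundance vector over nucleon-number offsets, mass of lightest isotope)."""
    table = _pmass.nist_mass[element]
    isotopes = [
        (num, m, ab) for num, (m, ab) in table.items() if num > 0 and ab > 0
    ]
    if not isotopes:
        raise ValueError(f"no isotope abundances for element {element!r}")
    base = min(num for num, _, _ in isotopes)
    size = max(num for num, _, _ in isotopes) - base + 1
    vec = np.zeros(size)
    for num, _, ab in isotopes:
        vec[num - base] = ab
    return vec, base


def _poly_pow(vec: np.ndarray, n: int, maxlen: int) -> np.ndarray:
    """vec convolved with itself n times, truncated to maxlen terms."""
    result = np.array([1.0])
    base = vec.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:maxlen]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:maxlen]
    return result


def isotope_distribution(
    comp: Mapping[str, int], n_peaks: int = 3
) -> np.ndarray:
    """Relative abundances of the first aggregated isotopologue peaks.

    Exact polynomial convolution of per-element natural-abundance
    distributions (no averagine approximation; compositions are always known
    here).  Normalized to max = 1.
    """
    maxlen = n_peaks + 8  # guard terms so truncation cannot bias the head
    dist = np.array([1.0])
    for element, count in comp.items():
        if count == 0:
            continue
        vec, _ = _isotope_offsets(element)
        dist = np.convolve(dist, _poly_pow(vec, int(count), maxlen))[:maxlen]
    dist = dist[:n_peaks]
    peak = dist.max()
    if peak > 0:
        dist = dist / peak
    return dist


def isotope_envelope(
    form: ModifiedPeptideForm, charge: int, n_peaks: int = 3
) -> IsotopeEnvelope:
    """Isotope envelope of a charged form from its exact composition."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    comp = composition(form)
    rel = isotope_distribution(comp, n_peaks=n_peaks)
    mono = monoisotopic_mass(form)
    mz0 = precursor_mz(mono, charge)
    mz = mz0 + np.arange(len(rel)) * NEUTRON_SPACING / charge
    return IsotopeEnvelope(mz=mz, intensity=rel)
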