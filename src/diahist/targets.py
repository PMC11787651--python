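"""Searchable target database for derivatized histone peptides.

Propionylation blocks trypsin at lysine, so digestion of derivatized histones
cleaves only after arginine (and not before proline) with zero missed
cleavages — the "trypsin derivatization [R|P]" rule.  On each digest peptide
the biological PTM search space is enumerated combinatorially, every
candidate is then derivatized, and forms whose precursors coincide in m/z
(positional isomers exactly, pseudo-isobaric pairs within a ppm tolerance)
are grouped for downstream fragment-based splitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import fasta as _pfasta
from pyteomics import mass as _pmass

from .chemistry import (
    Modification,
    ModificationRegistry,
    ModifiedPeptideForm,
    N_TERM,
    apply_propionylation,
    default_registry,
    monoisotopic_mass,
    precursor_mz,
)

__all__ = [
    "DigestPeptide",
    "IsomerGroup",
    "digest",
    "load_histones",
    "enumerate_forms",
    "group_isobaric",
    "build_target_table",
    "forms_from_table",
    "save_target_table",
    "load_target_table",
]


@dataclass(frozen=True)
class DigestPeptide:
    """One tryptic peptide in post-Met protein coordinates (1-based, inclusive)."""

    protein: str
    span: tuple[int, int]
    sequence: str


def digest(
    sequence: str, protein: str = "", offset: int = 1
) -> list[DigestPeptide]:
    """Cleave after R except before P; K is never cleaved (propionyl-blocked).

    Zero missed cleavages: the peptides partition the protein. ``offset`` is
    the protein coordinate of the first residue (1 after Met trimming).
    """
    for res in sequence:
        if res not in _pmass.std_aa_mass:
            raise ValueError(f"invalid residue code: {res!r}")
    peptides: list[DigestPeptide] = []
    start = 0
    for i, res in enumerate(sequence):
        at_end = i == len(sequence) - 1
        if res == "R" and (at_end or sequence[i + 1] != "P"):
            peptides.append(
                DigestPeptide(
                    protein=protein,
                    span=(offset + start, offset + i),
                    sequence=sequence[start : i + 1],
                )
            )
            start = i + 1
    if start < len(sequence):
        peptides.append(
            DigestPeptide(
                protein=protein,
                span=(offset + start, offset + len(sequence) - 1),
                sequence=sequence[start:],
            )
        )
    return peptides


def load_histones(path=None, trim_met: bool = True) -> dict[str, str]:
    """Protein id -> sequence from FASTA; bundled human histones by default.

    With ``trim_met`` (the histone convention) a leading initiator methionine
    is removed so that residue numbering matches names like "H3K27".
    """

    def _read(p):
        out = {}
        for header, seq in _pfasta.read(str(p)):
            pid = header.split()[0]
            if trim_met and seq.startswith("M"):
                seq = seq[1:]
            out[pid] = seq
        return out

    if path is not None:
        return _read(path)
    ref = resources.files("diahist.data").joinpath("histones.fasta")
    with resources.as_file(ref) as p:
        return _read(p)


def _eligible_sites(
    sequence: str, allowed_mods: Mapping[str, Iterable], registry: ModificationRegistry
) -> list[tuple[int, tuple[Modification, ...]]]:
    sites = []
    for pos, res in enumerate(sequence, start=1):
        if res not in allowed_mods:
            continue
        mods = tuple(
            m if isinstance(m, Modification) else registry[m]
            for m in allowed_mods[res]
        )
        mods = tuple(sorted(mods, key=lambda m: m.name))
        if mods:
            sites.append((pos, mods))
    return sites


def enumerate_forms(
    peptide: DigestPeptide | str,
    allowed_mods: Mapping[str, Iterable],
    max_mods: int = 1,
    registry: ModificationRegistry | None = None,
    include_unmodified: bool = False,
    derivatize: bool = True,
    charges: tuple[int, ...] = (2, 3, 4),
) -> list[ModifiedPeptideForm]:
    """All PTM placements with 1..max_mods modified sites, then derivatized.

    ``allowed_mods`` maps residue code -> modification names (or objects).
    Output order is deterministic: by modified positions, then mod names.
    With no eligible site (or ``include_unmodified``) the bare derivatized
    form is returned (first).
    """
    registry = registry or default_registry()
    if isinstance(peptide, str):
        peptide = DigestPeptide(protein="", span=(1, len(peptide)), sequence=peptide)

    def build(placements) -> ModifiedPeptideForm:
        form = ModifiedPeptideForm(
            protein=peptide.protein,
            span=peptide.span,
            sequence=peptide.sequence,
            placements=placements,
            charges=charges,
        )
        return apply_propionylation(form, registry) if derivatize else form

    sites = _eligible_sites(peptide.sequence, allowed_mods, registry)
    forms: list[ModifiedPeptideForm] = []
    if include_unmodified or not sites:
        forms.append(build({}))
    for size in range(1, max_mods + 1):
        for combo in itertools.combinations(sites, size):
            positions = [pos for pos, _ in combo]
            for assignment in itertools.product(*(mods for _, mods in combo)):
                forms.append(
                    build({pos: (mod,) for pos, mod in zip(positions, assignment)})
                )
    return forms


@dataclass
class IsomerGroup:
    """Forms of one backbone whose precursors coincide at a charge state."""

    forms: tuple[ModifiedPeptideForm, ...]
    charge: int

    def __post_init__(self) -> None:
        if not self.forms:
            raise ValueError("empty isomer group")
        backbones = {(f.protein, f.span, f.sequence) for f in self.forms}
        if len(backbones) > 1:
            raise ValueError("isomer group members must share a backbone")

    def __len__(self) -> int:
        return len(self.forms)

    @property
    def mzs(self) -> np.ndarray:
        return np.array(
            [precursor_mz(monoisotopic_mass(f), self.charge) for f in self.forms]
        )

    @property
    def mz(self) -> float:
        return float(self.mzs.mean())

    @property
    def sequence(self) -> str:
        return self.forms[0].sequence

    @property
    def candidate_sites(self) -> list[int]:
        """Peptide positions whose placements differ across members, sorted."""
        positions = sorted(
            {
                int(p)
                for f in self.forms
                for p in f.placements
                if p != N_TERM
            }
        )
        differing = []
        for pos in positions:
            variants = {f.mods_at(pos) for f in self.forms}
            if len(variants) > 1:
                differing.append(pos)
        return differing


def _sort_key(form: ModifiedPeptideForm):
    items = sorted(
        ((str(pos), tuple(m.name for m in mods)) for pos, mods in form.placements.items()),
    )
    return (form.protein, form.span, form.sequence, items)


def group_isobaric(
    forms: Sequence[ModifiedPeptideForm], charge: int, ppm_tol: float = 10.0
) -> list[IsomerGroup]:
    """Partition forms by precursor m/z proximity at ``ppm_tol``.

    Positional isomers (identical composition, hence identical m/z) always
    co-group; the me3/ac pseudo-isobaric pair (0.036 Da apart) separates at
    the default 10 ppm for typical histone peptides.  Single-linkage chaining
    on sorted m/z, so the result is independent of input order.
    """
    if not forms:
        return []
    decorated = sorted(
        ((precursor_mz(monoisotopic_mass(f), charge), f) for f in forms),
        key=lambda t: (t[0], _sort_key(t[1])),
    )
    groups: list[list[ModifiedPeptideForm]] = [[decorated[0][1]]]
    last_mz = decorated[0][0]
    for mz, form in decorated[1:]:
        if mz - last_mz <= ppm_tol * 1e-6 * mz:
            groups[-1].append(form)
        else:
            groups.append([form])
        last_mz = mz
    return [IsomerGroup(forms=tuple(g), charge=charge) for g in groups]


# ---------------------------------------------------------------------------
# target table (CSV) serialization
# ---------------------------------------------------------------------------

def _placements_str(form: ModifiedPeptideForm) -> str:
    parts = []
    keys = sorted(form.placements, key=lambda p: (p == N_TERM, int(p) if p != N_TERM else 0))
    for pos in keys:
        names = "+".join(m.name for m in form.mods_at(pos))
        parts.append(f"{pos}:{names}")
    return ";".join(parts)


def _placements_from_str(
    text: str, registry: ModificationRegistry
) -> dict[str | int, tuple[Modification, ...]]:
    out: dict[str | int, tuple[Modification, ...]] = {}
    if not text or text in ("-", "nan"):
        return out
    for part in text.split(";"):
        pos_s, names = part.split(":")
        pos: str | int = N_TERM if pos_s == N_TERM else int(pos_s)
        out[pos] = tuple(registry[n] for n in names.split("+"))
    return out


def build_target_table(
    forms: Sequence[ModifiedPeptideForm],
    charges: tuple[int, ...] = (2, 3, 4),
    ref_rts: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Flat per-form table with neutral mass and per-charge m/z columns."""
    rows = []
    for f in forms:
        mass = monoisotopic_mass(f)
        row = {
            "label": f.label,
            "protein": f.protein,
            "span_start": f.span[0],
            "span_end": f.span[1],
            "sequence": f.sequence,
            "placements": _placements_str(f),
            "neutral_mass": round(mass, 4),
        }
        for z in charges:
            row[f"mz_z{z}"] = round(precursor_mz(mass, z), 4)
        if ref_rts is not None:
            row["ref_rt"] = ref_rts.get(f.label, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def forms_from_table(
    table: pd.DataFrame, registry: ModificationRegistry | None = None
) -> list[ModifiedPeptideForm]:
    registry = registry or default_registry()
    forms = []
    for _, row in table.iterrows():
        forms.append(
            ModifiedPeptideForm(
                protein=row["protein"],
                span=(int(row["span_start"]), int(row["span_end"])),
                sequence=row["sequence"],
                placements=_placements_from_str(str(row["placements"]), registry),
            )
        )
    return forms


def save_target_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_target_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
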