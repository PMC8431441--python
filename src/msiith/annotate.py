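"""Peptide/protein annotation of spectral components by relative-tolerance
m/z matching against an LC-MS/MS-derived peptide library."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set

PROTON_MASS = 1.00728  # Da, mass added under the [M+H]+ convention

__all__ = [
    "PROTON_MASS",
    "PeptideEntry",
    "ComponentMatch",
    "ProteinSummary",
    "match_components",
    "summarize_proteins",
    "decoy_match_rate",
    "read_peptide_library",
    "write_peptide_library",
]


@dataclass(frozen=True)
class PeptideEntry:
    peptide_id: str
    sequence: str
    neutral_mass: float  # monoisotopic, Da
    protein_accession: str
    is_decoy: bool = False

    def __post_init__(self):
        if self.neutral_mass <= 0:
            raise ValueError(f"neutral_mass must be positive ({self.peptide_id})")


@dataclass(frozen=True)
class ComponentMatch:
    component_id: int
    component_center: float
    peptide_id: str
    expected_mz: float
    relative_error: float  # signed (center - expected) / expected
    protein_accession: str
    is_decoy: bool


@dataclass(frozen=True)
class ProteinSummary:
    protein_accession: str
    component_ids: tuple
    n_components: int


def match_components(
    components,
    library: Sequence[PeptideEntry],
    tolerance: float = 5e-4,
    charge_convention: str = "MH_plus",
) -> List[ComponentMatch]:
    """All (component, peptide) pairs within the relative mass tolerance.

    A match requires ``|center - m_expected| / m_expected <= tolerance``
    where ``m_expected = neutral_mass + 1.00728`` under ``MH_plus`` (the
    MALDI singly-protonated default) or the bare neutral mass under
    ``neutral``.  Matches are many-to-many by design and sorted by component
    id then absolute error; decoy entries are flagged through, not dropped.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not library:
        raise ValueError("peptide library is empty")
    if charge_convention not in ("MH_plus", "neutral"):
        raise ValueError(f"unknown charge convention {charge_convention!r}")
    delta = PROTON_MASS if charge_convention == "MH_plus" else 0.0

    matches: List[ComponentMatch] = []
    for comp in components:
        cid = comp.component_id
        center = comp.center
        for pep in library:
            expected = pep.neutral_mass + delta
            rel = (center - expected) / expected
            if abs(rel) <= tolerance:
                matches.append(
                    ComponentMatch(
                        component_id=cid,
                        component_center=center,
                        peptide_id=pep.peptide_id,
                        expected_mz=expected,
                        relative_error=rel,
                        protein_accession=pep.protein_accession,
                        is_decoy=pep.is_decoy,
                    )
                )
    matches.sort(key=lambda m: (m.component_id, abs(m.relative_error), m.peptide_id))
    return matches


def summarize_proteins(
    matches: Iterable[ComponentMatch],
    restrict_to: Optional[Set[int]] = None,
    include_decoys: bool = False,
) -> List[ProteinSummary]:
    """Distinct matched components per protein accession.

    ``restrict_to`` limits the tally to a component subset (e.g. a screening
    hit list).  Output is ordered by count descending, accession ascending.
    """
    per_protein = {}
    for m in matches:
        if m.is_decoy and not include_decoys:
            continue
        if restrict_to is not None and m.component_id not in restrict_to:
            continue
        per_protein.setdefault(m.protein_accession, set()).add(m.component_id)
    out = [
        ProteinSummary(acc, tuple(sorted(cids)), len(cids))
        for acc, cids in per_protein.items()
    ]
    out.sort(key=lambda s: (-s.n_components, s.protein_accession))
    return out


def decoy_match_rate(matches: Iterable[ComponentMatch]) -> float:
    """Fraction of matches hitting decoy entries (chance-match estimate)."""
    matches = list(matches)
    if not matches:
        return 0.0
    return sum(m.is_decoy for m in matches) / len(matches)


LIBRARY_COLUMNS = ["peptide_id", "sequence", "neutral_mass", "protein_accession", "is_decoy"]


def write_peptide_library(entries: Sequence[PeptideEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LIBRARY_COLUMNS)
        for e in entries:
            w.writerow([e.peptide_id, e.sequence, repr(e.neutral_mass), e.protein_accession, int(e.is_decoy)])


def read_peptide_library(path) -> List[PeptideEntry]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PeptideEntry(
                    peptide_id=row["peptide_id"],
                    sequence=row["sequence"],
                    neutral_mass=float(row["neutral_mass"]),
                    protein_accession=row["protein_accession"],
                    is_decoy=bool(int(row["is_decoy"])),
                )
            )
    return out
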