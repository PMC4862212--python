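"""In-silico tryptic digestion and peptide observability.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline.  A peptide counts as *observable* when its
monoisotopic m/z falls inside the instrument's full-scan window for at
least one of the allowed charge states.  The observable-peptide count is
the denominator of the emPAI index, so both rules are fixed, documented
conventions rather than tunable heuristics.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

PROTON_MASS = 1.007276

#: full-scan acquisition window (m/z) of the study's instrument method
DEFAULT_SCAN_RANGE = (300.0, 1800.0)
DEFAULT_CHARGES = (1, 2, 3)


def validate_sequence(sequence: str) -> None:
    """Reject sequences containing residues outside the 20-letter alphabet."""
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise ValueError(
            f"non-standard residue(s) {sorted(bad)!r} in sequence {sequence[:30]!r}..."
        )


def digest_protein(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Tryptic peptides of ``sequence`` in N->C order.

    Cleaves after K/R except before P.  With ``missed_cleavages = m`` the
    result also contains every join of up to ``m+1`` adjacent fragments,
    emitted in N->C order of the join's start position.
    """
    validate_sequence(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    fragments: list[str] = []
    start = 0
    for i, residue in enumerate(sequence):
        if residue in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])
    if missed_cleavages == 0:
        return fragments
    return _ordered_joins(fragments, missed_cleavages)


def _ordered_joins(fragments: list[str], missed_cleavages: int) -> list[str]:
    """All fragments first, then joins grouped by missed-cleavage count."""
    out: list[str] = list(fragments)
    for m in range(1, missed_cleavages + 1):
        for i in range(len(fragments) - m):
            out.append("".join(fragments[i : i + m + 1]))
    return out


@lru_cache(maxsize=100_000)
def monoisotopic_mass(peptide: str) -> float:
    """Neutral monoisotopic mass of a peptide (Da)."""
    return float(_pmass.fast_mass(peptide, ion_type="M", charge=0))


def peptide_mz(peptide: str, charge: int) -> float:
    """m/z of ``peptide`` at charge ``z``: (M + z*proton)/z."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (monoisotopic_mass(peptide) + charge * PROTON_MASS) / charge


def is_observable(
    peptide: str,
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> bool:
    """True if the peptide's m/z lies in the scan window at >=1 allowed charge."""
    low, high = scan_range
    return any(low <= peptide_mz(peptide, z) <= high for z in charges)


def count_observable_peptides(
    peptides: Iterable[str],
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> int:
    """Number of *distinct* peptides observable in the scan window.

    A peptide observable at several charges still counts once.
    """
    low, high = scan_range
    if not low < high:
        raise ValueError(f"invalid scan range {scan_range!r}")
    if not charges:
        raise ValueError("charge set must be non-empty")
    return sum(1 for p in set(peptides) if is_observable(p, scan_range, charges))
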