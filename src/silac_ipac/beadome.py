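"""Contaminant ("beadome") and abundance ("abundome") catalogues.

Control pull-downs with untagged lysate reveal which proteins stick to each
affinity resin non-specifically; proteins sticky on two or more chemically
distinct resins form the multi-resin beadome.  Crude-lysate identifications
ranked by emPAI — the exponentially modified protein abundance index,
``10^(N_observed / N_observable) - 1`` — give the abundome, the most
abundant proteins of the lysate.  The observable-peptide denominator comes
from an in-silico tryptic digest restricted to a mass window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pyteomics_mass

from .quant_io import ProteomeRecord

__all__ = [
    "EmPAIRecord",
    "BeadomeEntry",
    "digest",
    "cleavage_fragments",
    "peptide_mass",
    "count_observable",
    "observable_peptide_count",
    "empai_score",
    "build_abundome",
    "build_beadome",
    "multi_resin_beadome",
    "proteome_fraction",
    "DEFAULT_MASS_WINDOW",
]

#: Observable-peptide mass window in Da (typical LC-MS/MS detectability).
DEFAULT_MASS_WINDOW = (500.0, 3000.0)


@dataclass(frozen=True)
class EmPAIRecord:
    """emPAI abundance score of one protein.

    ``pai`` is N_observed / N_observable and ``empai = 10**pai - 1``; both
    are ``None`` for unscoreable proteins (no observable peptides).
    """

    accession: str
    n_observed: int
    n_observable: int
    pai: float | None
    empai: float | None


@dataclass(frozen=True)
class BeadomeEntry:
    """Membership of one sticky protein across control pull-down resins."""

    accession: str
    resins_observed: frozenset[str]
    in_abundome: bool = False

    def __post_init__(self) -> None:
        if not self.resins_observed:
            raise ValueError(
                f"beadome entry {self.accession!r} observed on no resin"
            )

    @property
    def n_resins(self) -> int:
        return len(self.resins_observed)


# ---------------------------------------------------------------------------
# in-silico tryptic digestion
# ---------------------------------------------------------------------------

def cleavage_fragments(sequence: str) -> list[str]:
    """Fully cleaved tryptic fragments, in N-to-C order.

    Trypsin cleaves C-terminal to K or R, except when the next residue is
    proline (the Mascot/Keil convention).  Concatenating the returned
    fragments reproduces the input sequence.
    """
    fragments: list[str] = []
    start = 0
    n = len(sequence)
    for i, residue in enumerate(sequence):
        if residue in "KR" and (i + 1 == n or sequence[i + 1] != "P"):
            fragments.append(sequence[start:i + 1])
            start = i + 1
    if start < n:
        fragments.append(sequence[start:])
    return fragments


def digest(sequence: str, missed_cleavages: int = 0) -> set[str]:
    """All tryptic peptides with up to ``missed_cleavages`` retained sites.

    Returns set semantics (repeated peptides collapse); the empty sequence
    yields the empty set.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    fragments = cleavage_fragments(sequence)
    peptides: set[str] = set()
    for i in range(len(fragments)):
        for j in range(i + 1, min(i + missed_cleavages + 2, len(fragments) + 1)):
            peptides.add("".join(fragments[i:j]))
    return peptides


def peptide_mass(peptide: str) -> float:
    """Monoisotopic neutral mass of a peptide in Da (residues + one water)."""
    if not peptide:
        raise ValueError("cannot compute the mass of an empty peptide")
    try:
        return float(_pyteomics_mass.fast_mass(peptide))
    except Exception as exc:  # non-canonical residue
        raise ValueError(f"cannot compute mass of {peptide!r}: {exc}") from exc


def count_observable(
    peptides: Iterable[str],
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
) -> int:
    """Number of distinct peptides whose mass lies in the closed window."""
    low, high = mass_window
    return sum(low <= peptide_mass(p) <= high for p in set(peptides))


def observable_peptide_count(
    record: ProteomeRecord,
    *,
    missed_cleavages: int = 2,
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
) -> int:
    """Observable tryptic peptides of a proteome entry (emPAI denominator).

    Peptides containing non-canonical residues are skipped (their masses
    are undefined for the residue table).
    """
    count = 0
    for peptide in digest(record.sequence, missed_cleavages):
        try:
            m = peptide_mass(peptide)
        except ValueError:
            continue
        if mass_window[0] <= m <= mass_window[1]:
            count += 1
    return count


# ---------------------------------------------------------------------------
# emPAI
# ---------------------------------------------------------------------------

def empai_score(accession: str, n_observed: int, n_observable: int) -> EmPAIRecord:
    """emPAI of one protein from observed/observable distinct peptide counts."""
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    if n_observable < 1:
        # unscoreable: reported with absent scores rather than dropped
        return EmPAIRecord(accession, n_observed, max(n_observable, 0), None, None)
    pai = n_observed / n_observable
    return EmPAIRecord(accession, n_observed, n_observable, pai, 10.0 ** pai - 1.0)


def build_abundome(
    records: Iterable[EmPAIRecord],
    top_n: int = 150,
) -> list[EmPAIRecord]:
    """Top ``top_n`` proteins by descending emPAI.

    Ties break by larger observed-peptide count, then accession;
    unscoreable records are excluded.
    """
    scoreable = [r for r in records if r.empai is not None]
    scoreable.sort(key=lambda r: (-r.empai, -r.n_observed, r.accession))
    return scoreable[:top_n]


# ---------------------------------------------------------------------------
# beadome
# ---------------------------------------------------------------------------

def build_beadome(
    identifications: Mapping[str, Iterable[str]],
    *,
    abundome: Iterable = (),
) -> list[BeadomeEntry]:
    """Union of control pull-down identifications with per-resin membership.

    ``identifications`` maps each resin label to the accessions identified
    in its control-only pull-down.  ``abundome`` (accessions or
    :class:`EmPAIRecord`) marks entries that are also lysate-abundant.
    """
    membership: dict[str, set[str]] = {}
    for resin, accessions in identifications.items():
        for acc in accessions:
            membership.setdefault(acc, set()).add(resin)
    abundant = {getattr(a, "accession", a) for a in abundome}
    return [
        BeadomeEntry(
            accession=acc,
            resins_observed=frozenset(resins),
            in_abundome=acc in abundant,
        )
        for acc, resins in sorted(membership.items())
    ]


def multi_resin_beadome(
    entries: Iterable[BeadomeEntry],
    min_resins: int = 2,
) -> list[BeadomeEntry]:
    """Subset of the beadome sticky on at least ``min_resins`` resins."""
    if min_resins < 1:
        raise ValueError("min_resins must be >= 1")
    return [e for e in entries if e.n_resins >= min_resins]


def proteome_fraction(n_proteins: int, proteome_size: int) -> float:
    """Percentage of a reference proteome represented by ``n_proteins``."""
    if proteome_size < 1:
        raise ValueError("proteome_size must be >= 1")
    return 100.0 * n_proteins / proteome_size
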