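"""CpG presence calling from per-site alignment windows.

Each array CpG is represented by a 122-column alignment window: 60 bp of
flank on either side of the focal dinucleotide, which occupies columns 61-62
(1-based).  A taxon is called ``present`` when its focal columns read exactly
``CG``, ``absent`` when both columns are ungapped nucleotides that do not
form CG, and ``missing`` when either column is a gap/N or the taxon row is
absent from the window.

Windows come from two independent alignment sources; a site enters the
phylogenetic analysis only when both sources exist, agree at every taxon,
and no taxon is missing (strict concordance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import DataError, UsageError
from .phylo import FOCAL_TAXON

logger = logging.getLogger(__name__)

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing"

WINDOW_LENGTH = 122
#: 1-based columns of the focal CpG dinucleotide within a window.
FOCAL_COLUMNS = (61, 62)

SOURCES = ("source_A", "source_B")

_NUCLEOTIDES = set("ACGT")
_ALPHABET = set("ACGTN-")


@dataclass
class AlignmentWindow:
    """Per-taxon aligned sequences around one CpG site, from one source."""

    site_id: str
    source: str
    sequences: dict[str, str] = field(default_factory=dict)
    length: int = WINDOW_LENGTH
    focal_columns: tuple[int, int] = FOCAL_COLUMNS

    def validate(self) -> None:
        for taxon, seq in self.sequences.items():
            if len(seq) != self.length:
                raise DataError(
                    f"{self.site_id}/{self.source}: row {taxon} has length "
                    f"{len(seq)}, expected {self.length}"
                )
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise DataError(
                    f"{self.site_id}/{self.source}: row {taxon} has symbols "
                    f"{sorted(bad)}"
                )


@dataclass
class PresenceVector:
    """Per-taxon CpG state for one site."""

    site_id: str
    states: dict[str, str]


def call_presence(window: AlignmentWindow, taxa: Sequence[str]) -> PresenceVector:
    """Call present/absent/missing for every taxon from one window.

    Soft-masked (lowercase) bases are read as their uppercase nucleotide.
    The human row must carry CG at the focal columns; anything else means
    the window does not belong to the manifest site and is a data error.
    """
    window.validate()
    i, j = window.focal_columns[0] - 1, window.focal_columns[1] - 1
    states: dict[str, str] = {}
    for taxon in taxa:
        seq = window.sequences.get(taxon)
        if seq is None:
            states[taxon] = MISSING
            continue
        a, b = seq[i].upper(), seq[j].upper()
        if a in "N-" or b in "N-":
            states[taxon] = MISSING
        elif (a, b) == ("C", "G"):
            states[taxon] = PRESENT
        elif a in _NUCLEOTIDES and b in _NUCLEOTIDES:
            states[taxon] = ABSENT
        else:  # pragma: no cover - excluded by validate()
            states[taxon] = MISSING
    if states.get(FOCAL_TAXON) != PRESENT:
        raise DataError(
            f"{window.site_id}/{window.source}: human row lacks CG at focal "
            f"columns {window.focal_columns} (manifest/window mismatch)"
        )
    return PresenceVector(window.site_id, states)


@dataclass(frozen=True)
class DropRecord:
    site_id: str
    reason: str  # discordant | missing-data | single-source


def reconcile_sources(
    a: PresenceVector, b: PresenceVector, mode: str = "strict"
) -> PresenceVector | DropRecord:
    """Combine the two alignment sources for one site.

    In strict mode the site is retained only when both vectors agree at every
    taxon and no taxon is missing in either; otherwise a :class:`DropRecord`
    with a single reason code is returned (missing data takes precedence over
    discordance, since a missing taxon makes agreement untestable).
    """
    if mode != "strict":
        raise UsageError(f"unknown reconciliation mode: {mode!r}")
    if a.site_id != b.site_id:
        raise UsageError(f"site_id mismatch: {a.site_id!r} vs {b.site_id!r}")
    taxa = set(a.states) | set(b.states)
    if any(
        a.states.get(t, MISSING) == MISSING or b.states.get(t, MISSING) == MISSING
        for t in taxa
    ):
        return DropRecord(a.site_id, "missing-data")
    if any(a.states[t] != b.states[t] for t in taxa):
        return DropRecord(a.site_id, "discordant")
    return PresenceVector(a.site_id, dict(a.states))


def reconcile_all(
    windows: Mapping[tuple[str, str], AlignmentWindow],
    site_ids: Iterable[str],
    taxa: Sequence[str],
) -> tuple[list[PresenceVector], list[DropRecord]]:
    """Call and reconcile every manifest site; account for every drop.

    Returns retained presence vectors and the exhaustive drop log
    (retained + dropped = input).
    """
    retained: list[PresenceVector] = []
    dropped: list[DropRecord] = []
    for site_id in site_ids:
        wa = windows.get((site_id, SOURCES[0]))
        wb = windows.get((site_id, SOURCES[1]))
        if wa is None or wb is None:
            dropped.append(DropRecord(site_id, "single-source"))
            continue
        result = reconcile_sources(
            call_presence(wa, taxa), call_presence(wb, taxa)
        )
        if isinstance(result, DropRecord):
            dropped.append(result)
        else:
            retained.append(result)
    logger.info(
        "reconciled %d sites: %d retained, %d dropped",
        len(retained) + len(dropped),
        len(retained),
        len(dropped),
    )
    return retained, dropped


# ---------------------------------------------------------------------------
# FASTA I/O — record ids are "taxon|site_id|source"
# ---------------------------------------------------------------------------


def read_windows_fasta(path) -> dict[tuple[str, str], AlignmentWindow]:
    """Read per-site alignment windows keyed by (site_id, source)."""
    windows: dict[tuple[str, str], AlignmentWindow] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise DataError(
                f"FASTA id {record.id!r} is not of the form taxon|site_id|source"
            )
        taxon, site_id, source = parts
        key = (site_id, source)
        window = windows.setdefault(key, AlignmentWindow(site_id, source))
        if taxon in window.sequences:
            raise DataError(f"duplicate row {taxon} for {site_id}/{source}")
        window.sequences[taxon] = str(record.seq)
    return windows


def write_windows_fasta(windows: Iterable[AlignmentWindow], path) -> None:
    with open(path, "w") as fh:
        for window in windows:
            for taxon in sorted(window.sequences):
                fh.write(f">{taxon}|{window.site_id}|{window.source}\n")
                fh.write(window.sequences[taxon] + "\n")
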