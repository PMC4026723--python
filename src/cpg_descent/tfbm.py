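"""Consensus-index-weighted PWM scanning of CpG-centered windows.

A position count matrix over ACGT is summarised per column by the consensus
index

    Ci(i) = (100 / ln 4) * sum_b f(i,b) ln f(i,b) + 100,

which is 0 for a uniform column and 100 for a single-base column.  The
*core* of a matrix is the contiguous run of four columns with the largest
total Ci.  A candidate W-mer is scored by

    mat_sim = sum_i Ci(i) f(i, b_i) / sum_i Ci(i) max_b f(i,b),

i.e. a Ci-weighted average of the observed base frequencies, normalised so
the per-column consensus base scores 1.  ``core_sim`` is the same ratio
restricted to the core columns and acts as a fast pre-filter.

Windows are the 122-bp human sequences around array CpGs (focal columns
61-62); both strands are scanned and hits are deduplicated per (matrix,
interval).  A hit "overlaps" the CpG when its interval covers column 61 or
62.  Stringency tiers on mat_sim (>0.80, >0.90, >0.95, =1) follow the
convention that a score of 1 means the consensus base at every weighted
column.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import FOCAL_COLUMNS, WINDOW_LENGTH
from .errors import DataError, UsageError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CORE_WIDTH = 4

DEFAULT_CORE_THRESHOLD = 0.75
DEFAULT_MAT_THRESHOLD = 0.80
TIER_LABELS = (">0.80", ">0.90", ">0.95", "=1")
TIER_CUTOFFS = (0.80, 0.90, 0.95, 1.0)
_ONE_TOL = 1e-9


@dataclass
class PositionWeightMatrix:
    """A TRANSFAC-style count matrix with derived Ci weights and core."""

    matrix_id: str
    family: str
    counts: np.ndarray  # (W, 4) float, per-position ACGT counts

    frequencies: np.ndarray = field(init=False)
    ci: np.ndarray = field(init=False)
    core_start: int = field(init=False)  # 0-based index of 4-column core

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise DataError(f"{self.matrix_id}: counts must be (W, 4)")
        if self.counts.shape[0] < CORE_WIDTH:
            raise DataError(f"{self.matrix_id}: width must be >= {CORE_WIDTH}")
        if (self.counts < 0).any():
            raise DataError(f"{self.matrix_id}: negative counts")
        totals = self.counts.sum(axis=1)
        if (totals <= 0).any():
            raise DataError(f"{self.matrix_id}: empty matrix column")
        self.frequencies = self.counts / totals[:, None]
        self.ci = consensus_index(self.frequencies)
        windows = np.convolve(self.ci, np.ones(CORE_WIDTH), mode="valid")
        self.core_start = int(np.argmax(windows))  # leftmost maximum

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))

    def reverse_complement(self) -> "PositionWeightMatrix":
        # reverse positions, swap A<->T and C<->G columns
        return PositionWeightMatrix(
            self.matrix_id, self.family, self.counts[::-1, [3, 2, 1, 0]]
        )


def consensus_index(frequencies: np.ndarray) -> np.ndarray:
    """Per-column Ci in [0, 100]; 0 iff uniform, 100 iff single-base."""
    f = np.asarray(frequencies, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f), 0.0)
    return (100.0 / math.log(4)) * terms.sum(axis=1) + 100.0


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=int)
    except KeyError:
        bad = sorted(set(seq) - set(BASES))
        raise DataError(f"non-ACGT symbols in sequence: {bad}") from None


def _similarity(pwm: PositionWeightMatrix, coded: np.ndarray, lo: int, hi: int) -> float:
    ci = pwm.ci[lo:hi]
    freqs = pwm.frequencies[lo:hi]
    denom = float((ci * freqs.max(axis=1)).sum())
    if denom == 0.0:
        return 0.0
    num = float((ci * freqs[np.arange(hi - lo), coded[lo:hi]]).sum())
    return num / denom


def matrix_similarity(pwm: PositionWeightMatrix, sequence: str) -> float:
    """Ci-weighted similarity of a W-mer to the matrix, in [0, 1]."""
    coded = _encode(sequence)
    if len(coded) != pwm.width:
        raise DataError(
            f"sequence length {len(coded)} != matrix width {pwm.width}"
        )
    return _similarity(pwm, coded, 0, pwm.width)


def core_similarity(pwm: PositionWeightMatrix, sequence: str) -> float:
    """Similarity restricted to the 4-column core."""
    coded = _encode(sequence)
    if len(coded) != pwm.width:
        raise DataError(
            f"sequence length {len(coded)} != matrix width {pwm.width}"
        )
    return _similarity(pwm, coded, pwm.core_start, pwm.core_start + CORE_WIDTH)


@dataclass(frozen=True)
class MotifHit:
    matrix_id: str
    family: str
    site_id: str
    strand: str  # '+' or '-'
    start: int  # 1-based, inclusive, + strand window coordinates
    end: int
    mat_sim: float
    core_sim: float
    overlaps_cpg: bool


_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_RC)[::-1]


def scan_window(
    pwm: PositionWeightMatrix,
    window: str,
    site_id: str = "",
    core_threshold: float = DEFAULT_CORE_THRESHOLD,
    mat_threshold: float = DEFAULT_MAT_THRESHOLD,
    focal_columns: tuple[int, int] = FOCAL_COLUMNS,
) -> list[MotifHit]:
    """Slide the matrix over both strands of one CpG window.

    Hits require core_sim >= core_threshold and mat_sim > mat_threshold.
    Minus-strand hits are reported in plus-strand coordinates; hits sharing
    (matrix, interval) are deduplicated keeping the higher-scoring strand
    (plus strand on ties).
    """
    if len(window) != WINDOW_LENGTH:
        raise DataError(
            f"window length {len(window)} != expected {WINDOW_LENGTH}"
        )
    L, W = len(window), pwm.width
    by_interval: dict[tuple[int, int], MotifHit] = {}
    for strand in "+-":
        seq = window.upper() if strand == "+" else reverse_complement(window)
        coded = _encode(seq)
        for offset in range(L - W + 1):
            segment = coded[offset : offset + W]
            core = _similarity(pwm, segment, pwm.core_start, pwm.core_start + CORE_WIDTH)
            if core < core_threshold:
                continue
            mat = _similarity(pwm, segment, 0, W)
            if not mat > mat_threshold:
                continue
            if strand == "+":
                start = offset + 1
            else:
                start = L - (offset + W) + 1
            end = start + W - 1
            overlaps = start <= focal_columns[0] <= end or start <= focal_columns[1] <= end
            hit = MotifHit(
                pwm.matrix_id, pwm.family, site_id, strand, start, end,
                mat, core, overlaps,
            )
            key = (start, end)
            prev = by_interval.get(key)
            if prev is None or (hit.mat_sim, hit.strand == "+") > (
                prev.mat_sim, prev.strand == "+"
            ):
                by_interval[key] = hit
    return sorted(
        by_interval.values(), key=lambda h: (h.start, h.strand != "+", h.matrix_id)
    )


def scan_many(
    pwms: Sequence[PositionWeightMatrix],
    windows: Mapping[str, str],
    core_threshold: float = DEFAULT_CORE_THRESHOLD,
    mat_threshold: float = DEFAULT_MAT_THRESHOLD,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for site_id, window in windows.items():
        for pwm in pwms:
            hits.extend(
                scan_window(pwm, window, site_id, core_threshold, mat_threshold)
            )
    return hits


# ---------------------------------------------------------------------------
# Stringency tiers and Table-style summaries
# ---------------------------------------------------------------------------


def _in_tier(mat_sim: float, cutoff: float) -> bool:
    if cutoff >= 1.0:
        return abs(mat_sim - 1.0) <= _ONE_TOL
    return mat_sim > cutoff


@dataclass
class TfbmSummary:
    """Stringency-tier counts and tier-1 (mat_sim = 1) breakdowns."""

    tier_hits: dict[str, int]
    tier_sites: dict[str, int]  # unique CpG sites per tier
    tier1_by_family: dict[str, int]
    tier1_by_branch: dict[str, int]


def tier_and_summarize(
    hits: Iterable[MotifHit],
    origins: Mapping[str, str] | None = None,
    tiers: Sequence[float] = TIER_CUTOFFS,
) -> TfbmSummary:
    """Summarise CpG-overlapping hits per stringency tier.

    Only hits overlapping the focal CpG are counted.  ``origins`` maps
    site_id → origin branch for the per-branch breakdown of the strictest
    tier; sites without an origin are grouped under ``unassigned``.
    """
    overlapping = [h for h in hits if h.overlaps_cpg]
    labels = [
        "=1" if c >= 1.0 else f">{c:.2f}" for c in tiers
    ]
    tier_hits: dict[str, int] = {}
    tier_sites: dict[str, int] = {}
    for label, cutoff in zip(labels, tiers):
        members = [h for h in overlapping if _in_tier(h.mat_sim, cutoff)]
        tier_hits[label] = len(members)
        tier_sites[label] = len({h.site_id for h in members})
    top = [h for h in overlapping if _in_tier(h.mat_sim, 1.0)]
    by_family: dict[str, int] = {}
    by_branch: dict[str, int] = {}
    for h in top:
        by_family[h.family] = by_family.get(h.family, 0) + 1
        branch = (origins or {}).get(h.site_id, "unassigned")
        by_branch[branch] = by_branch.get(branch, 0) + 1
    return TfbmSummary(tier_hits, tier_sites, by_family, by_branch)


def summarize_tier1_table(df: pd.DataFrame) -> dict[str, object]:
    """Summarise a table of top-stringency hits (family, site, gene, branch).

    Returns record count, unique CpG sites, number of matrix families, and
    per-branch record counts.
    """
    required = {"matrix_family", "site_id", "branch"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"tier-1 table lacks columns: {sorted(missing)}")
    return {
        "n_records": int(len(df)),
        "n_unique_sites": int(df["site_id"].nunique()),
        "n_families": int(df["matrix_family"].nunique()),
        "branch_counts": df["branch"].value_counts().to_dict(),
    }


def load_tier1_fixture() -> pd.DataFrame:
    """The packaged table of 22 top-stringency motif hits over array CpGs."""
    text = (
        resources.files("cpg_descent.data").joinpath("tier1_motif_hits.tsv").read_text()
    )
    return pd.read_csv(io.StringIO(text), sep="\t")


# ---------------------------------------------------------------------------
# TRANSFAC-style matrix I/O
# ---------------------------------------------------------------------------


def read_transfac(path_or_text) -> list[PositionWeightMatrix]:
    """Read count matrices in a minimal TRANSFAC-like format.

    Records are separated by ``//``; recognised rows are ``ID`` (matrix id),
    ``NA`` (family / name), ``P0`` (column header, ignored), and numbered
    rows with four counts in A C G T order.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(path_or_text)
    matrices: list[PositionWeightMatrix] = []
    matrix_id, family, rows = None, "", []

    def flush() -> None:
        nonlocal matrix_id, family, rows
        if matrix_id is not None:
            if not rows:
                raise DataError(f"matrix {matrix_id} has no count rows")
            matrices.append(
                PositionWeightMatrix(matrix_id, family or matrix_id, np.array(rows))
            )
        matrix_id, family, rows = None, "", []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("//"):
            flush()
        elif line.startswith("ID"):
            flush()
            matrix_id = line.split(None, 1)[1].strip()
        elif line.startswith("NA"):
            family = line.split(None, 1)[1].strip()
        elif line.startswith("P0") or line.startswith("PO"):
            continue
        else:
            fields = line.split()
            if matrix_id is None:
                raise DataError("count row before any ID line")
            try:
                rows.append([float(x) for x in fields[1:5]])
            except (ValueError, IndexError):
                raise DataError(f"unparseable TRANSFAC row: {line!r}") from None
    flush()
    if not matrices:
        raise DataError("no matrices found")
    return matrices


def write_transfac(pwms: Sequence[PositionWeightMatrix], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.matrix_id}\nNA {pwm.family}\nP0 A C G T\n")
            for i, row in enumerate(pwm.counts, start=1):
                fh.write(
                    f"{i:02d} " + " ".join(f"{v:g}" for v in row) + "\n"
                )
            fh.write("//\n")
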