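"""Origin-branch assignment on human descent and cumulative presence curves.

Every retained site (human-present, CI = 1, unique MPR) either gained its
CpG on one of the eight stem lineages leading to humans, or was already
present in the amniote ancestor.  A retained non-invariant character carries
exactly one change: a 0→1 gain on a root→human edge places the origin on the
corresponding stem; a 1→0 loss elsewhere on the tree (or an invariant
all-present character) means the CpG predates the mammal stem and is binned
as ``pre_mammal``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import UsageError
from .parsimony import ParsimonyResult
from .phylo import (
    BRANCH_NAMES,
    FOCAL_TAXON,
    PRE_MAMMAL,
    BranchSegment,
    PhyloTree,
    human_path_segment_map,
)


@dataclass(frozen=True)
class OriginAssignment:
    site_id: str
    origin: str  # a BRANCH_NAMES entry or "pre_mammal"


def assign_origin(
    result: ParsimonyResult,
    tree: PhyloTree,
    segments: Sequence[BranchSegment],
) -> OriginAssignment:
    """Place one retained site's CpG gain on human descent."""
    if not result.retained:
        raise UsageError(
            f"{result.site_id}: origin assignment requires a retained "
            "(CI=1, unique-MPR) reconstruction"
        )
    if result.final_states[FOCAL_TAXON] != 1:
        raise UsageError(f"{result.site_id}: focal taxon is not CpG-present")

    if result.change_count == 0:
        return OriginAssignment(result.site_id, PRE_MAMMAL)

    # retained + both states observed => exactly one change edge
    (edge,) = result.change_edges
    edge_segments = human_path_segment_map(tree, segments)
    if edge in edge_segments:
        parent, child = edge
        if not (
            result.final_states[parent] == 0 and result.final_states[child] == 1
        ):
            raise UsageError(
                f"{result.site_id}: change on human-path edge {edge} is a "
                "loss, impossible for a human-present site"
            )
        return OriginAssignment(result.site_id, edge_segments[edge].name)
    # single change off the human path: must be a loss from ancestral presence
    return OriginAssignment(result.site_id, PRE_MAMMAL)


#: Origins at or older than index i of BRANCH_NAMES were present at the
#: ancestor that ends segment i.
def cumulative_presence(
    assignments: Sequence[OriginAssignment],
    segments: Sequence[BranchSegment],
) -> dict[str, float]:
    """Percent of sites already present at each successive human ancestor.

    The ancestor closing segment ``i`` carries every site whose origin is
    segment ``i`` or older (including ``pre_mammal``).  Keys are
    ``after_<segment>`` labels ordered oldest→youngest; the final entry
    (after the human terminal branch, i.e. at present) is always 100.0.
    Values are percentages rounded to one decimal.
    """
    if not assignments:
        raise UsageError("cumulative_presence requires at least one assignment")
    order = {name: i for i, name in enumerate(BRANCH_NAMES)}
    total = len(assignments)
    counts = [0] * len(BRANCH_NAMES)
    older = 0
    for a in assignments:
        if a.origin == PRE_MAMMAL:
            older += 1
        else:
            counts[order[a.origin]] += 1
    curve: dict[str, float] = {}
    running = older
    for seg in segments:
        running += counts[order[seg.name]]
        curve[f"after_{seg.name}"] = round(100.0 * running / total, 1)
    return curve


def origin_counts(
    assignments: Sequence[OriginAssignment],
) -> dict[str, int]:
    """Per-branch origin counts over BRANCH_NAMES plus pre_mammal.

    Partition property: the values sum to the number of assignments.
    """
    counts = {name: 0 for name in (*BRANCH_NAMES, PRE_MAMMAL)}
    for a in assignments:
        counts[a.origin] += 1
    return counts


def split_by_flag(
    assignments: Sequence[OriginAssignment],
    ptsd_flags: Mapping[str, bool],
) -> tuple[list[OriginAssignment], list[OriginAssignment]]:
    """(all sites, flagged subset) — the subset is also part of the whole."""
    subset = [a for a in assignments if ptsd_flags.get(a.site_id, False)]
    return list(assignments), subset
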