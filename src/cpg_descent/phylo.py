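"""Fixed-topology mammalian tree, divergence-time calibration, and manifest I/O.

The analysis runs on a rooted 12-taxon amniote tree (chicken outgroup, human
focal taxon).  The path from the root to the human tip is partitioned into
eight named stem lineages ("branch segments"), each bounded by two successive
last common ancestors with calibrated ages in millions of years ago (Mya):

====================  ==========  ========  =============
segment               start (Mya)  end (Mya)  duration (Myr)
====================  ==========  ========  =============
mammal                     324.5      217.8          106.7
theria                     217.8      190.0           27.8
placental                  190.0       92.0           98.0
euarchontoglires            92.0       83.3            8.7
primate                     83.3       25.4           57.9
ape                         25.4       18.0            7.4
human_chimp                 18.0        7.2           10.8
human_terminal               7.2        0.0            7.2
====================  ==========  ========  =============

Segments tile the interval [root age, 0] exactly, so every point in time on
human descent belongs to exactly one segment.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Sequence

import dendropy
import pandas as pd

from .errors import CalibrationError, DataError, TreeError

logger = logging.getLogger(__name__)

FOCAL_TAXON = "human"
OUTGROUP_TAXON = "chicken"

#: Stem-lineage names in order from the root toward the human tip.
BRANCH_NAMES = (
    "mammal",
    "theria",
    "placental",
    "euarchontoglires",
    "primate",
    "ape",
    "human_chimp",
    "human_terminal",
)

#: Category for sites already present in the amniote ancestor (or whose only
#: change is a loss off the human path): older than every named segment.
PRE_MAMMAL = "pre_mammal"


class TreeNode:
    """A node of a rooted tree; tips carry taxon names, internals clade labels."""

    __slots__ = ("name", "children", "parent")

    def __init__(self, name: str, children: list["TreeNode"] | None = None):
        self.name = name
        self.children: list[TreeNode] = children or []
        self.parent: TreeNode | None = None
        for child in self.children:
            child.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r})"


class PhyloTree:
    """Rooted tree with unique node labels and a well-defined root→human path."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._by_name: dict[str, TreeNode] = {}
        for node in self.postorder():
            if node.name in self._by_name:
                raise TreeError(f"duplicate node label: {node.name!r}")
            self._by_name[node.name] = node

    # -- traversal -----------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        def walk(node: TreeNode) -> Iterator[TreeNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def taxa(self) -> list[str]:
        """Tip labels in postorder."""
        return [n.name for n in self.postorder() if n.is_leaf]

    def node(self, name: str) -> TreeNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise TreeError(f"no node labelled {name!r}") from None

    def depth(self, node: TreeNode) -> int:
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def path_to(self, taxon: str) -> list[TreeNode]:
        """Nodes from the root to the named tip, inclusive."""
        node = self.node(taxon)
        path = [node]
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return list(reversed(path))

    def human_path_edges(self) -> list[tuple[str, str]]:
        """(parent, child) label pairs along root→human, oldest first."""
        path = self.path_to(FOCAL_TAXON)
        return [(a.name, b.name) for a, b in zip(path, path[1:])]

    def leaves_under(self, node: TreeNode) -> set[str]:
        return {n.name for n in _subtree_postorder(node) if n.is_leaf}

    # -- serialisation -------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.name}"

        return render(self.root) + ";"


def _subtree_postorder(node: TreeNode) -> Iterator[TreeNode]:
    for child in node.children:
        yield from _subtree_postorder(child)
    yield node


def read_tree(newick_text: str) -> PhyloTree:
    """Parse a rooted Newick tree and validate it for this analysis.

    Requirements: unique tip labels, the focal taxon ``human`` and the
    outgroup ``chicken`` both present, and every internal node with at least
    two children.  Unlabelled internal nodes receive deterministic ``nodeN``
    labels in postorder.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"Newick parse failure: {exc}") from exc

    tips = [leaf.taxon.label.replace(" ", "_") for leaf in dtree.leaf_node_iter()]
    if len(tips) != len(set(tips)):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise TreeError(f"duplicate tip labels: {', '.join(dupes)}")
    if FOCAL_TAXON not in tips:
        raise TreeError("focal taxon absent: tree has no 'human' tip")
    if OUTGROUP_TAXON not in tips:
        raise TreeError("outgroup taxon absent: tree has no 'chicken' tip")

    counter = 0

    def convert(dnode) -> TreeNode:
        nonlocal counter
        if dnode.is_leaf():
            return TreeNode(dnode.taxon.label.replace(" ", "_"))
        children = [convert(c) for c in dnode.child_nodes()]
        if len(children) < 2:
            raise TreeError("internal node with a single child (unifurcation)")
        label = dnode.label
        if not label:
            counter += 1
            label = f"node{counter}"
        return TreeNode(label, children)

    return PhyloTree(convert(dtree.seed_node))


def default_tree() -> PhyloTree:
    """The packaged 12-taxon tree (chicken outgroup through human)."""
    text = resources.files("cpg_descent.data").joinpath("default_tree.nwk").read_text()
    return read_tree(text)


# ---------------------------------------------------------------------------
# Branch segments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchSegment:
    """A stem lineage on human descent bounded by two calibrated ancestors."""

    name: str
    start_age: float  # Mya, older bound
    end_age: float  # Mya, younger bound

    @property
    def duration(self) -> float:
        """Length of the segment in Myr."""
        return self.start_age - self.end_age

    def contains_age(self, age: float) -> bool:
        """True if ``age`` falls in the half-open interval (end, start]."""
        return self.end_age < age <= self.start_age


def build_branch_segments(
    calibration: Sequence[tuple[str, float]],
) -> list[BranchSegment]:
    """Turn an ordered ancestor→age table into the eight named segments.

    ``calibration`` lists nine (ancestor label, age in Mya) points from the
    root of the tree down to the human tip (age 0); consecutive points bound
    one segment each, named per :data:`BRANCH_NAMES`.
    """
    if len(calibration) != len(BRANCH_NAMES) + 1:
        raise CalibrationError(
            f"expected {len(BRANCH_NAMES) + 1} calibration points, "
            f"got {len(calibration)}"
        )
    ages = [float(age) for _, age in calibration]
    for older, younger in zip(ages, ages[1:]):
        if not older > younger:
            raise CalibrationError(
                f"ages must strictly decrease toward the present: {older} !> {younger}"
            )
    if ages[-1] != 0.0:
        raise CalibrationError(f"final calibration point must be age 0, got {ages[-1]}")
    return [
        BranchSegment(name, start, end)
        for name, start, end in zip(BRANCH_NAMES, ages, ages[1:])
    ]


def default_calibration() -> list[tuple[str, float]]:
    """The packaged divergence-time table (ancestor label, age Mya)."""
    text = (
        resources.files("cpg_descent.data")
        .joinpath("default_calibration.tsv")
        .read_text()
    )
    df = pd.read_csv(io.StringIO(text), sep="\t")
    return list(zip(df["ancestor"], df["age_mya"].astype(float)))


def default_segments() -> list[BranchSegment]:
    return build_branch_segments(default_calibration())


def segment_for_age(segments: Sequence[BranchSegment], age: float) -> BranchSegment:
    """The unique segment whose interval (end, start] contains ``age``."""
    for seg in segments:
        if seg.contains_age(age):
            return seg
    raise CalibrationError(f"age {age} Mya outside (0, {segments[0].start_age}]")


def human_path_segment_map(
    tree: PhyloTree, segments: Sequence[BranchSegment]
) -> dict[tuple[str, str], BranchSegment]:
    """Associate each root→human edge with its stem lineage, oldest first."""
    edges = tree.human_path_edges()
    if len(edges) != len(segments):
        raise TreeError(
            f"root→human path has {len(edges)} edges but {len(segments)} "
            "segments are defined"
        )
    return dict(zip(edges, segments))


# ---------------------------------------------------------------------------
# Site manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteRecord:
    """One methylation-array CpG probe: location, proximal gene, trait flag."""

    site_id: str
    chromosome: str
    position: int
    gene: str
    ptsd_flag: bool


MANIFEST_COLUMNS = ("site_id", "chrom", "pos", "gene", "ptsd_flag")


def read_site_manifest(path_or_buffer) -> list[SiteRecord]:
    """Read a tab-delimited CpG site manifest into validated records."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"manifest lacks columns: {', '.join(missing)}")
    if df.empty:
        logger.warning("site manifest is empty")
        return []
    dupes = df["site_id"][df["site_id"].duplicated()].unique()
    if len(dupes):
        raise DataError(f"duplicate site_id in manifest: {', '.join(dupes)}")
    records = []
    for row in df.itertuples(index=False):
        pos = int(row.pos)
        if pos < 1:
            raise DataError(f"non-positive position for {row.site_id}: {pos}")
        flag = str(row.ptsd_flag).strip().lower() in {"1", "true", "yes"}
        gene = "" if pd.isna(row.gene) else str(row.gene)
        records.append(SiteRecord(row.site_id, str(row.chrom), pos, gene, flag))
    return records


def write_site_manifest(records: Sequence[SiteRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.site_id, r.chromosome, r.position, r.gene, int(r.ptsd_flag))
            for r in records
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
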