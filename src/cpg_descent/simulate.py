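"""Tree-consistent synthetic data with known origin-branch truth.

The generator emulates the structure of the real inputs — per-site 122-bp
alignment windows from two sources, an array-style site manifest, TRANSFAC
count matrices, and gene→term annotations — while recording each site's
true origin so parameter-recovery can be scored exactly.

Each site's CpG gain is placed on a human-descent stem with probability
proportional to (gain intensity x stem duration), or in the pre-mammal
ancestor by its own weight.  The default weights reproduce the cumulative
presence profile reported for trauma-associated array CpGs: 7% of sites
predate the human/rodent ancestor, 48% the human/macaque ancestor, 73% the
human/orangutan ancestor, and 93% the human/chimpanzee ancestor, with 7%
arising on the human terminal branch.  Losses are deamination-style CG→TG
flips in individual non-human taxa; a human-lineage loss is never simulated
(array sites are human CpGs by definition).  Flank columns mutate
independently per taxon and never touch the focal columns, so the focal
character stays well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import FOCAL_COLUMNS, SOURCES, WINDOW_LENGTH, AlignmentWindow
from .errors import UsageError
from .phylo import (
    BRANCH_NAMES,
    FOCAL_TAXON,
    PRE_MAMMAL,
    BranchSegment,
    PhyloTree,
    SiteRecord,
    default_segments,
    default_tree,
    human_path_segment_map,
)
from .tfbm import BASES, PositionWeightMatrix

#: Default per-stem origin probabilities (sum with pre_mammal weight = 1);
#: chosen to match the reported cumulative presence curve (7/48/73/93%).
DEFAULT_ORIGIN_WEIGHTS: dict[str, float] = {
    PRE_MAMMAL: 0.02,
    "mammal": 0.015,
    "theria": 0.01,
    "placental": 0.015,
    "euarchontoglires": 0.01,
    "primate": 0.41,
    "ape": 0.25,
    "human_chimp": 0.20,
    "human_terminal": 0.07,
}


def default_gain_intensities(
    segments: Sequence[BranchSegment] | None = None,
) -> dict[str, float]:
    """Gains/Myr per stem implied by the default origin weights."""
    segments = segments or default_segments()
    return {
        s.name: DEFAULT_ORIGIN_WEIGHTS[s.name] / s.duration for s in segments
    }


@dataclass
class SimulationConfig:
    """All knobs of the site simulator; see module docstring for defaults."""

    n_sites: int = 500
    gain_intensity: dict[str, float] = field(default_factory=default_gain_intensities)
    pre_mammal_weight: float = DEFAULT_ORIGIN_WEIGHTS[PRE_MAMMAL]
    loss_prob: float = 0.0  # per present non-human taxon
    flank_sub_prob: float = 0.05  # per flank column per non-human taxon
    discordance_prob: float = 0.0  # per site, one taxon flipped in source_B
    ptsd_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 0:
            raise UsageError("n_sites must be >= 0")
        for name, prob in (
            ("loss_prob", self.loss_prob),
            ("flank_sub_prob", self.flank_sub_prob),
            ("discordance_prob", self.discordance_prob),
            ("ptsd_fraction", self.ptsd_fraction),
        ):
            if not 0.0 <= prob <= 1.0:
                raise UsageError(f"{name} must be in [0, 1], got {prob}")
        if self.pre_mammal_weight < 0:
            raise UsageError("pre_mammal_weight must be >= 0")
        missing = set(BRANCH_NAMES) - set(self.gain_intensity)
        if missing:
            raise UsageError(f"gain_intensity lacks stems: {sorted(missing)}")
        if any(v < 0 for v in self.gain_intensity.values()):
            raise UsageError("gain intensities must be >= 0")
        total = self.pre_mammal_weight + sum(
            self.gain_intensity[n] for n in BRANCH_NAMES
        )
        if total <= 0:
            raise UsageError("at least one origin weight must be positive")


@dataclass(frozen=True)
class TruthRecord:
    site_id: str
    origin: str
    losses: tuple[str, ...]  # taxa with simulated CG→TG loss
    discordant: bool
    ptsd_flag: bool


def origin_probabilities(
    config: SimulationConfig, segments: Sequence[BranchSegment]
) -> dict[str, float]:
    """Normalised origin distribution: intensity x duration per stem."""
    weights = {PRE_MAMMAL: config.pre_mammal_weight}
    for seg in segments:
        weights[seg.name] = config.gain_intensity[seg.name] * seg.duration
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def _random_window(rng: np.random.Generator) -> str:
    seq = rng.choice(list(BASES), size=WINDOW_LENGTH)
    seq[FOCAL_COLUMNS[0] - 1] = "C"
    seq[FOCAL_COLUMNS[1] - 1] = "G"
    return "".join(seq)


_BASE_TO_I = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.array(list(BASES))


def _mutate_flanks(seq: str, prob: float, rng: np.random.Generator) -> str:
    flips = rng.random(len(seq)) < prob
    flips[FOCAL_COLUMNS[0] - 1] = flips[FOCAL_COLUMNS[1] - 1] = False
    if not flips.any():
        return seq
    chars = np.array(list(seq))
    idx = np.flatnonzero(flips)
    current = np.array([_BASE_TO_I[c] for c in chars[idx]])
    shift = rng.integers(1, 4, size=len(idx))  # never the same base
    chars[idx] = _BASE_ARR[(current + shift) % 4]
    return "".join(chars)


def _set_focal(seq: str, present: bool) -> str:
    i, j = FOCAL_COLUMNS[0] - 1, FOCAL_COLUMNS[1] - 1
    chars = list(seq)
    # deamination-style loss: CG → TG
    chars[i], chars[j] = ("C", "G") if present else ("T", "G")
    return "".join(chars)


def simulate_sites(
    config: SimulationConfig,
    tree: PhyloTree | None = None,
    segments: Sequence[BranchSegment] | None = None,
) -> tuple[
    list[SiteRecord],
    list[AlignmentWindow],
    list[AlignmentWindow],
    list[TruthRecord],
]:
    """Generate the manifest, dual-source windows, and the truth table."""
    config.validate()
    tree = tree or default_tree()
    segments = list(segments or default_segments())
    rng = np.random.default_rng(config.seed)

    probs = origin_probabilities(config, segments)
    categories = [PRE_MAMMAL] + [s.name for s in segments]
    pvec = np.array([probs[c] for c in categories])

    edge_map = human_path_segment_map(tree, segments)
    clade_of: dict[str, set[str]] = {}
    for (parent, child), seg in edge_map.items():
        clade_of[seg.name] = tree.leaves_under(tree.node(child))
    all_taxa = set(tree.taxa)
    taxa_order = tree.taxa

    manifest: list[SiteRecord] = []
    windows_a: list[AlignmentWindow] = []
    windows_b: list[AlignmentWindow] = []
    truth: list[TruthRecord] = []

    for i in range(config.n_sites):
        site_id = f"cg{i + 1:08d}"
        origin = categories[int(rng.choice(len(categories), p=pvec))]
        present = set(all_taxa) if origin == PRE_MAMMAL else set(clade_of[origin])

        losses = []
        for taxon in taxa_order:
            if taxon == FOCAL_TAXON or taxon not in present:
                continue
            if rng.random() < config.loss_prob:
                present.discard(taxon)
                losses.append(taxon)

        human_seq = _random_window(rng)
        seqs_a: dict[str, str] = {}
        for taxon in taxa_order:
            if taxon == FOCAL_TAXON:
                seqs_a[taxon] = human_seq
            else:
                mutated = _mutate_flanks(human_seq, config.flank_sub_prob, rng)
                seqs_a[taxon] = _set_focal(mutated, taxon in present)

        seqs_b = dict(seqs_a)
        discordant = False
        if rng.random() < config.discordance_prob:
            candidates = [t for t in taxa_order if t != FOCAL_TAXON]
            victim = candidates[int(rng.choice(len(candidates)))]
            seqs_b[victim] = _set_focal(seqs_b[victim], victim not in present)
            discordant = True

        windows_a.append(AlignmentWindow(site_id, SOURCES[0], seqs_a))
        windows_b.append(AlignmentWindow(site_id, SOURCES[1], seqs_b))
        ptsd = bool(rng.random() < config.ptsd_fraction)
        manifest.append(
            SiteRecord(site_id, "chr1", 1000 + 200 * i, f"GENE{i + 1:05d}", ptsd)
        )
        truth.append(TruthRecord(site_id, origin, tuple(losses), discordant, ptsd))

    return manifest, windows_a, windows_b, truth


def truth_table_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.site_id, t.origin, ",".join(t.losses), int(t.discordant), int(t.ptsd_flag))
            for t in truth
        ],
        columns=["site_id", "origin", "losses", "discordant", "ptsd_flag"],
    )


def simulate_matrices(
    n: int,
    widths: Sequence[int] | int = 8,
    conservation: float = 0.9,
    seed: int = 0,
) -> list[PositionWeightMatrix]:
    """Random count matrices with a controllable conservation profile.

    Each column mixes a single consensus base (weight ``conservation``) with
    a uniform background; conservation 1 gives single-base columns (Ci =
    100), conservation 0 uniform columns (Ci = 0).  The first matrix always
    carries a central CG in its consensus so that CpG-overlapping hits are
    reachable.
    """
    if not 0.0 <= conservation <= 1.0:
        raise UsageError("conservation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(widths, int):
        widths = [widths] * n
    if any(w < 4 for w in widths):
        raise UsageError("matrix widths must be >= 4")
    if len(widths) != n:
        raise UsageError("widths must match n")
    pwms: list[PositionWeightMatrix] = []
    for m in range(n):
        w = widths[m]
        consensus = [int(c) for c in rng.choice(4, size=w)]
        if m == 0:
            mid = w // 2 - 1
            consensus[mid], consensus[mid + 1] = 1, 2  # C, G
        counts = np.full((w, 4), 100.0 * (1.0 - conservation) / 4.0)
        for i, b in enumerate(consensus):
            counts[i, b] += 100.0 * conservation
        pwms.append(PositionWeightMatrix(f"M{m + 1:03d}", f"FAM{m + 1:03d}", counts))
    return pwms


def simulate_annotations(
    genes: Sequence[str],
    n_terms: int = 20,
    base_rate: float = 0.1,
    planted: tuple[Sequence[str], str, float] | None = None,
    seed: int = 0,
):
    """Random gene→term incidence with an optional planted enrichment.

    ``planted = (branch_genes, term, effect)`` raises the planted term's
    carriage probability among ``branch_genes`` from ``base_rate`` to
    ``base_rate + effect * (1 - base_rate)``; effect 0 leaves the term
    exchangeable with the background (null).
    """
    from .enrichment import AnnotationMap

    if not genes:
        raise UsageError("genes must be nonempty")
    rng = np.random.default_rng(seed)
    amap = AnnotationMap()
    planted_genes: set[str] = set()
    planted_term, effect = None, 0.0
    if planted is not None:
        branch_genes, planted_term, effect = planted
        planted_genes = set(branch_genes)
    for t in range(n_terms):
        term = f"TERM{t + 1:04d}"
        for gene in genes:
            rate = base_rate
            if term == planted_term and gene in planted_genes:
                rate = base_rate + effect * (1.0 - base_rate)
            if rng.random() < rate:
                amap.add(gene, term)
    return amap
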