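"""Gene-neighborhood scanning for SusC/SusD-anchored loci (PUL detection).

KEGG locus tags embed a per-genome gene index, but genomes number their
genes in steps of 1, 5 or 10, sometimes with gaps.  Distances between genes
are therefore measured in *ranks* (position in the sorted index list), not
index units; :func:`infer_step` recovers each genome's numbering step so the
two coincide on regular genomes.

A gene counts as a SusD homolog through a three-tier evidence ladder:

* ``SusD-ID`` — the SusD KEGG Orthology accession K21572 (strongest),
* ``SusD-D``  — a SusD-associated domain annotation ("RagB", "SusD-like"),
* ``SusD-N``  — a SusD/RagB mention in the gene name or free annotation.

:func:`scan` walks every gene carrying a filtered hit of the target domain,
looks ±w genes (default 5) around it, and reports the best SusD evidence in
the window; a hit anywhere in the window marks the target as PUL-encoded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .architecture import DEFAULT_CUTOFF, apply_aliases, dedupe_hits, filter_hits
from .errors import InsufficientDataError, LookupError_, PulcensusError, StateError
from .io import Dataset, DomainHit, GeneRecord

DEFAULT_WINDOW = 5

#: evidence tiers, strongest first
TIER_ID = "SusD-ID"
TIER_D = "SusD-D"
TIER_N = "SusD-N"
TIER_NONE = "none"
_TIER_RANK = {TIER_ID: 0, TIER_D: 1, TIER_N: 2, TIER_NONE: 3}

POSITION_CLASSES = ("susE-like", "susF-like", "susG-like", "other", "none")


@dataclass(frozen=True)
class MarkerConfig:
    """Strings that identify the PUL marker gene (SusD by default).

    ``ko`` is matched exactly; domain and name strings are case-insensitive
    substrings after whitespace collapsing.  Supplying different strings
    retargets the scan at any other marker.
    """

    ko: str = "K21572"
    domain_strings: tuple[str, ...] = ("RagB", "SusD-like")
    name_strings: tuple[str, ...] = ("SusD", "RagB")


@dataclass(frozen=True)
class StepModel:
    """A genome's locus-tag numbering step."""

    genome_id: str
    step: int
    regular: bool


@dataclass(frozen=True)
class SusDEvidence:
    gene_id: str
    tier: str
    matched_text: str = ""

    @property
    def is_hit(self) -> bool:
        return self.tier != TIER_NONE


@dataclass(frozen=True)
class SusDNeighbor:
    gene_id: str
    tier: str
    offset: int  # signed rank offset of the marker gene relative to the target


@dataclass(frozen=True)
class VicinityResult:
    target_gene_id: str
    window: int
    neighbor_gene_ids: tuple[str, ...]
    susd_hit: Optional[SusDNeighbor]
    position_class: str = "none"
    n_domain_copies: int = 1

    @property
    def pul_positive(self) -> bool:
        return self.susd_hit is not None


@dataclass
class ScanSummary:
    target_domain: str
    window: int
    cutoff: float
    n_targets: int
    n_pul_positive: int
    tier_counts: dict[str, int] = field(default_factory=dict)

    @property
    def fraction(self) -> float:
        return self.n_pul_positive / self.n_targets if self.n_targets else 0.0


def infer_step(indices: Sequence[int], genome_id: str = "") -> StepModel:
    """Infer a genome's numbering step as the mode of consecutive differences.

    Ties break toward the smaller step; ``regular`` is True iff every
    consecutive difference equals the step.
    """
    idx = sorted(indices)
    if len(idx) < 2:
        raise InsufficientDataError(
            f"genome {genome_id or '?'}: need >= 2 gene indices to infer a step"
        )
    diffs = [b - a for a, b in zip(idx, idx[1:])]
    counts = Counter(diffs)
    top = max(counts.values())
    step = min(d for d, c in counts.items() if c == top)
    return StepModel(genome_id=genome_id, step=step, regular=len(counts) == 1)


def infer_steps(dataset: Dataset) -> dict[str, StepModel]:
    """Step model per genome (genomes with a single gene are skipped)."""
    out = {}
    for gid in dataset.genome_ids():
        indices = [g.gene_index for g in dataset.genes_in_genome(gid)]
        if len(indices) >= 2:
            out[gid] = infer_step(indices, gid)
    return out


def neighbors(dataset: Dataset, target: str, w: int = DEFAULT_WINDOW) -> list[str]:
    """Gene ids within rank distance 1..w of the target, ordered -w..+w.

    Distances are ranks in the genome's sorted index list, so step-5/step-10
    numbering and isolated gaps do not distort the window.  Genome edges
    truncate it.
    """
    if w < 0:
        raise PulcensusError(f"window must be >= 0, got {w}")
    target_gene = dataset.gene(target)
    ordered = dataset.genes_in_genome(target_gene.genome_id)
    ranks = {g.gene_id: i for i, g in enumerate(ordered)}
    r = ranks[target]
    lo, hi = max(0, r - w), min(len(ordered) - 1, r + w)
    return [ordered[i].gene_id for i in range(lo, hi + 1) if i != r]


def _collapse_ws(s: str) -> str:
    return " ".join(s.split()).lower()


def susd_evidence(
    gene: GeneRecord,
    hits: Sequence[DomainHit] = (),
    markers: MarkerConfig = MarkerConfig(),
) -> SusDEvidence:
    """Classify a gene's SusD evidence; the strongest applicable tier wins."""
    if gene.ko is not None and gene.ko == markers.ko:
        return SusDEvidence(gene.gene_id, TIER_ID, gene.ko)

    domain_texts = [h.domain for h in hits if h.gene_id == gene.gene_id]
    for needle in markers.domain_strings:
        n = _collapse_ws(needle)
        for text in domain_texts:
            if n in _collapse_ws(text):
                return SusDEvidence(gene.gene_id, TIER_D, text)

    for needle in markers.name_strings:
        n = _collapse_ws(needle)
        for text in (gene.name, gene.annotation):
            if text and n in _collapse_ws(text):
                return SusDEvidence(gene.gene_id, TIER_N, text)

    return SusDEvidence(gene.gene_id, TIER_NONE)


def classify_position(
    result: VicinityResult, dataset: Dataset, markers: MarkerConfig = MarkerConfig()
) -> str:
    """Name the target's slot downstream of the susC/susD pair.

    With the susC gene sitting on the far side of susD, "downstream" is the
    direction leading away from the pair.  A target d genes downstream of
    susD maps to susE-like (d=1), susF-like (d=2), susG-like (d=3); anything
    else — including targets upstream of the pair — is "other".  Without
    strand information the direction is oriented by locating a susC-like
    gene adjacent to susD; absent that, increasing gene index is taken as
    downstream.
    """
    if not result.pul_positive:
        raise StateError("classify_position requires a pul-positive result")

    susd_id = result.susd_hit.gene_id
    genome = dataset.gene(susd_id).genome_id
    ordered = dataset.genes_in_genome(genome)
    ranks = {g.gene_id: i for i, g in enumerate(ordered)}
    r_susd = ranks[susd_id]
    r_target = ranks[result.target_gene_id]

    direction = _downstream_direction(ordered, r_susd)
    d = (r_target - r_susd) * direction
    return {1: "susE-like", 2: "susF-like", 3: "susG-like"}.get(d, "other")


_SUSC_STRINGS = ("susc", "tonb-dependent")
_SUSC_KO = "K21573"


def _downstream_direction(ordered: Sequence[GeneRecord], r_susd: int) -> int:
    """+1 if downstream is increasing rank, -1 if decreasing.

    susC adjacent at rank-1 places the pair upstream, so downstream is +1;
    susC at rank+1 flips it.  Defaults to +1 when no susC-like neighbor is
    found.
    """

    def looks_susc(g: GeneRecord) -> bool:
        if g.ko == _SUSC_KO:
            return True
        text = _collapse_ws(f"{g.name} {g.annotation}")
        return any(s in text for s in _SUSC_STRINGS)

    if r_susd - 1 >= 0 and looks_susc(ordered[r_susd - 1]):
        return 1
    if r_susd + 1 < len(ordered) and looks_susc(ordered[r_susd + 1]):
        return -1
    return 1


def scan(
    dataset: Dataset,
    target_domain: str,
    w: int = DEFAULT_WINDOW,
    cutoff: float = DEFAULT_CUTOFF,
    markers: MarkerConfig = MarkerConfig(),
    aliases=None,
) -> tuple[list[VicinityResult], ScanSummary]:
    """Scan ±w genes around every gene carrying the target domain.

    One result per target *gene* (a gene with several copies of the domain
    is still one target; the copy count rides along).  Among multiple marker
    neighbors the best tier wins, ties broken by smaller |offset|, then
    upstream (negative offset).  An unknown domain yields an empty result
    list, not an error.
    """
    by_gene = dataset.hits_by_gene()
    results: list[VicinityResult] = []
    tier_counts = Counter()

    for gene_id in sorted(dataset.genes):
        surviving = dedupe_hits(apply_aliases(filter_hits(by_gene[gene_id], cutoff), aliases))
        copies = sum(1 for h in surviving if h.domain == target_domain)
        if copies == 0:
            continue

        nbr_ids = neighbors(dataset, gene_id, w)
        genome = dataset.gene(gene_id).genome_id
        ordered = dataset.genes_in_genome(genome)
        ranks = {g.gene_id: i for i, g in enumerate(ordered)}
        r0 = ranks[gene_id]

        best: Optional[SusDNeighbor] = None
        for nid in nbr_ids:
            ev = susd_evidence(
                dataset.genes[nid],
                apply_aliases(filter_hits(by_gene[nid], cutoff), aliases),
                markers,
            )
            if not ev.is_hit:
                continue
            cand = SusDNeighbor(nid, ev.tier, ranks[nid] - r0)
            if best is None or _neighbor_key(cand) < _neighbor_key(best):
                best = cand

        result = VicinityResult(
            target_gene_id=gene_id,
            window=w,
            neighbor_gene_ids=tuple(nbr_ids),
            susd_hit=best,
            n_domain_copies=copies,
        )
        if best is not None:
            result = VicinityResult(
                target_gene_id=gene_id,
                window=w,
                neighbor_gene_ids=tuple(nbr_ids),
                susd_hit=best,
                position_class=classify_position(result, dataset, markers),
                n_domain_copies=copies,
            )
            tier_counts[best.tier] += 1
        results.append(result)

    summary = ScanSummary(
        target_domain=target_domain,
        window=w,
        cutoff=cutoff,
        n_targets=len(results),
        n_pul_positive=sum(r.pul_positive for r in results),
        tier_counts=dict(tier_counts),
    )
    return results, summary


def _neighbor_key(n: SusDNeighbor) -> tuple:
    # best tier, then closest, then upstream preferred
    return (_TIER_RANK[n.tier], abs(n.offset), 0 if n.offset < 0 else 1)
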