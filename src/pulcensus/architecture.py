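"""Canonical domain-architecture strings with overlap grouping.

A protein's filtered domain hits are grouped into connected components of
the pairwise-overlap relation (two hits overlap when the intersection covers
at least ``min_overlap_frac`` of the shorter hit).  Groups are rendered in
N→C order joined by ``" + "``; co-overlapping domains within a group are
joined by ``"|"`` (``"I"`` in paper-style typesetting).  A configured
merge pair — by default the frequently co-called DUF1735/DUF4973 — renders
as the primary name plus ``"*"``, e.g. ``DUF1735*``.

Example labels: ``DUF1735* + LamG3``, ``DUF1735 + DUF1735 + F5/8-typeC``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CoordinateError, FormatError, PulcensusError
from .io import DomainHit, GeneRecord

#: inclusive E-value cutoff used throughout the census
DEFAULT_CUTOFF = 1e-4

#: minimum fraction of the shorter hit that must be covered to call overlap
DEFAULT_MIN_OVERLAP_FRAC = 0.5

#: overlap groups rendered as "<primary>*" instead of "A|B"
DEFAULT_STAR_MERGE: dict[frozenset, str] = {
    frozenset({"DUF1735", "DUF4973"}): "DUF1735",
}

#: domain-name normalisation applied before grouping; keys are source-db
#: spellings, values the short names used in census tables
DEFAULT_ALIASES: dict[str, str] = {
    "Laminin_G_3": "LamG3",
    "F5_F8_type_C": "F5/8-typeC",
    "Glyco_hydro_18": "GH18",
    "Glyco_hydro_16": "GH16",
    "Glyco_hydro_43": "GH43",
    # short names map to themselves so an alias pass is idempotent
    "LamG3": "LamG3",
    "F5/8-typeC": "F5/8-typeC",
    "GH18": "GH18",
    "GH16": "GH16",
    "GH43": "GH43",
    "DUF1735": "DUF1735",
    "DUF4361": "DUF4361",
    "DUF5627": "DUF5627",
    "DUF4973": "DUF4973",
    "GLUG": "GLUG",
    "BACON": "BACON",
    "BACON_2": "BACON_2",
}

GROUP_SEP = " + "
OVERLAP_SEP = "|"
PAPER_OVERLAP_SEP = "I"


@dataclass(frozen=True)
class Architecture:
    """Ordered overlap-grouped domain layout of one protein."""

    gene_id: str
    groups: tuple[tuple[str, ...], ...]
    label: str
    n_terminal_domain: str
    multimodular: bool

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def domains(self) -> list[str]:
        return [d for grp in self.groups for d in grp]


def filter_hits(hits: Sequence[DomainHit], cutoff: float = DEFAULT_CUTOFF) -> list[DomainHit]:
    """Keep hits with E-value <= cutoff (inclusive), preserving order.

    Hits without an E-value (annotation-only evidence) are kept: they carry
    no score to filter on.
    """
    if cutoff <= 0:
        raise PulcensusError(f"cutoff must be positive, got {cutoff}")
    return [h for h in hits if h.evalue is None or h.evalue <= cutoff]


def dedupe_hits(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Collapse hits sharing (domain, start, end), keeping the lowest E-value."""
    best: dict[tuple, DomainHit] = {}
    order: list[tuple] = []
    for h in hits:
        key = (h.gene_id, h.domain, h.start, h.end)
        if key not in best:
            best[key] = h
            order.append(key)
        else:
            old = best[key]
            old_e = float("inf") if old.evalue is None else old.evalue
            new_e = float("inf") if h.evalue is None else h.evalue
            if new_e < old_e:
                best[key] = h
    return [best[k] for k in order]


def apply_aliases(
    hits: Sequence[DomainHit], aliases: Optional[Mapping[str, str]] = None
) -> list[DomainHit]:
    """Rename domains through the alias map (exact match after trimming)."""
    if aliases is None:
        aliases = DEFAULT_ALIASES
    out = []
    for h in hits:
        name = h.domain.strip()
        renamed = aliases.get(name, name)
        out.append(h if renamed == h.domain else
                   DomainHit(h.gene_id, renamed, h.start, h.end, h.evalue, h.source))
    return out


def _overlaps(a: DomainHit, b: DomainHit, frac: float) -> bool:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    shorter = min(a.length, b.length)
    return inter >= frac * shorter


def group_overlaps(
    hits: Sequence[DomainHit], min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC
) -> list[list[DomainHit]]:
    """Partition one gene's hits into connected components of the overlap relation.

    Within a group hits are ordered by (start, domain name); groups are
    ordered by their minimum start coordinate.
    """
    if not 0 < min_overlap_frac <= 1:
        raise PulcensusError(f"min_overlap_frac must be in (0,1], got {min_overlap_frac}")
    hits = list(hits)
    for h in hits:
        if h.start is None:
            raise CoordinateError(f"hit {h.gene_id}/{h.domain} has no coordinates")

    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _overlaps(hits[i], hits[j], min_overlap_frac):
                parent[find(i)] = find(j)

    comps: dict[int, list[DomainHit]] = {}
    for i, h in enumerate(hits):
        comps.setdefault(find(i), []).append(h)

    groups = [sorted(c, key=lambda h: (h.start, h.domain)) for c in comps.values()]
    groups.sort(key=lambda grp: min(h.start for h in grp))
    return groups


def _render_group(
    names: Sequence[str],
    star_merge: Mapping[frozenset, str],
    paper_style: bool,
) -> str:
    if len(names) >= 2 and frozenset(names) in star_merge:
        return star_merge[frozenset(names)] + "*"
    sep = PAPER_OVERLAP_SEP if paper_style else OVERLAP_SEP
    return sep.join(names)


def canonical_architecture(
    gene: GeneRecord,
    hits: Sequence[DomainHit],
    cutoff: float = DEFAULT_CUTOFF,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    star_merge: Optional[Mapping[frozenset, str]] = None,
    aliases: Optional[Mapping[str, str]] = None,
    paper_style: bool = False,
) -> Architecture:
    """Filter, dedupe, group and render one gene's hits into an Architecture.

    Repeated domains are kept per occurrence (``DUF1735 + DUF1735``).  An
    empty surviving hit set yields an empty label and ``multimodular=False``.
    """
    if star_merge is None:
        star_merge = DEFAULT_STAR_MERGE
    mine = [h for h in hits if h.gene_id == gene.gene_id]
    survivors = dedupe_hits(apply_aliases(filter_hits(mine, cutoff), aliases))
    survivors = [h for h in survivors if h.start is not None]
    if not survivors:
        return Architecture(gene.gene_id, (), "", "", False)

    groups = group_overlaps(survivors, min_overlap_frac)
    name_groups = tuple(tuple(h.domain for h in grp) for grp in groups)
    label = GROUP_SEP.join(
        _render_group(grp, star_merge, paper_style) for grp in name_groups
    )
    return Architecture(
        gene_id=gene.gene_id,
        groups=name_groups,
        label=label,
        n_terminal_domain=name_groups[0][0],
        multimodular=len(name_groups) >= 2,
    )


def has_n_terminal(arch: Architecture, domain: str) -> bool:
    """True iff ``domain`` is a member of the protein's first overlap group."""
    return bool(arch.groups) and domain in arch.groups[0]


def parse_label(
    label: str, star_merge: Optional[Mapping[frozenset, str]] = None
) -> list[list[str]]:
    """Invert a canonical label back into its name groups.

    Star groups expand to their full merge pair in sorted order (the
    within-group coordinate order is not recoverable from the label).
    """
    if star_merge is None:
        star_merge = DEFAULT_STAR_MERGE
    if not label:
        return []
    primary_to_pair = {v: sorted(k) for k, v in star_merge.items()}
    groups: list[list[str]] = []
    for chunk in label.split(GROUP_SEP):
        if chunk.endswith("*"):
            primary = chunk[:-1]
            if primary not in primary_to_pair:
                raise FormatError(f"unknown star-merged group {chunk!r}")
            groups.append(list(primary_to_pair[primary]))
        else:
            groups.append(chunk.split(OVERLAP_SEP))
    return groups


def architectures_for_dataset(
    dataset, target_domain: Optional[str] = None, **kwargs
) -> list[Architecture]:
    """Canonical architecture per gene; optionally only genes carrying a domain.

    ``target_domain`` restricts to genes whose surviving hits include that
    domain (after aliasing) — the census population of a domain-centric table.
    """
    by_gene = dataset.hits_by_gene()
    out = []
    for gene_id in sorted(dataset.genes):
        arch = canonical_architecture(dataset.genes[gene_id], by_gene[gene_id], **kwargs)
        if target_domain is None or target_domain in arch.domains():
            out.append(arch)
    return out
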