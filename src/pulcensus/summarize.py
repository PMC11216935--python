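"""Census arithmetic: frequency tables, copy numbers, taxonomy rollups.

All printed percentages and means use half-away-from-zero rounding at the
final decimal (31.75 -> 31.8), matching how census tables are typeset;
banker's rounding is deliberately not used.  Three count modes — domain
copies, proteins, genomes — are distinct and labeled as such in output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .architecture import (
    DEFAULT_CUTOFF,
    Architecture,
    apply_aliases,
    dedupe_hits,
    filter_hits,
)
from .errors import PulcensusError
from .io import Dataset


def _round_half_away(x: Decimal, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(x.quantize(q, rounding=ROUND_HALF_UP))


def percentage(n: int, total: int, decimals: int = 1) -> float:
    """100*n/total, half-away-from-zero at ``decimals`` places."""
    if total <= 0:
        raise PulcensusError(f"total must be positive, got {total}")
    if not 0 <= n <= total:
        raise PulcensusError(f"n={n} outside [0, {total}]")
    return _round_half_away(Decimal(100 * n) / Decimal(total), decimals)


def fold_change(n: int, baseline: int, decimals: int = 1) -> float:
    """n/baseline, half-away-from-zero at ``decimals`` places."""
    if baseline <= 0:
        raise PulcensusError(f"baseline must be positive, got {baseline}")
    return _round_half_away(Decimal(n) / Decimal(baseline), decimals)


@dataclass(frozen=True)
class FrequencyRow:
    key: str
    n: int
    pct: float


@dataclass(frozen=True)
class FrequencyTable:
    rows: tuple[FrequencyRow, ...]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.key, r.n, r.pct) for r in self.rows], columns=["key", "n", "pct"]
        )

    def as_dict(self) -> dict[str, int]:
        return {r.key: r.n for r in self.rows}


def frequency_table(counts: dict[str, int], min_n: int = 1,
                    other_label: Optional[str] = None) -> FrequencyTable:
    """Build a sorted frequency table, collapsing rows with n < min_n.

    Rows sort by count descending then key; the collapsed row, labeled
    ``"Other (n <= min_n-1)"`` unless overridden, is appended last.
    Percentages are over the full total including collapsed rows.
    """
    if not counts:
        raise PulcensusError("empty census")
    total = sum(counts.values())
    kept = {k: v for k, v in counts.items() if v >= min_n}
    dropped = total - sum(kept.values())
    rows = [
        FrequencyRow(k, v, percentage(v, total))
        for k, v in sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    if dropped:
        label = other_label or f"Other (n <= {min_n - 1})"
        rows.append(FrequencyRow(label, dropped, percentage(dropped, total)))
    return FrequencyTable(tuple(rows), total)


def architecture_table(
    archs: Sequence[Architecture], min_n: int = 1, other_label: Optional[str] = None
) -> FrequencyTable:
    """Frequency of canonical architecture labels over proteins.

    The total counts domain-bearing proteins (one per architecture), not
    individual domain copies.
    """
    labeled = [a for a in archs if a.label]
    if not labeled:
        raise PulcensusError("empty census")
    return frequency_table(Counter(a.label for a in labeled), min_n, other_label)


@dataclass(frozen=True)
class CopyNumberSummary:
    table: pd.DataFrame  # genome_id, species, n_proteins, n_domains, mean
    mean_domains_per_genome: float
    n_genomes: int


def copy_number_table(
    dataset: Dataset,
    target_domain: str,
    cutoff: float = DEFAULT_CUTOFF,
    aliases=None,
) -> CopyNumberSummary:
    """Per-genome copy numbers of a domain: proteins, domain copies, copies/protein.

    Genomes without a surviving copy are excluded.  The global mean is domain
    copies per genome over the included genomes.
    """
    per_genome: dict[str, list[int]] = {}
    species: dict[str, str] = {}
    for gene_id, hits in dataset.hits_by_gene().items():
        surviving = dedupe_hits(apply_aliases(filter_hits(hits, cutoff), aliases))
        copies = sum(1 for h in surviving if h.domain == target_domain)
        if copies == 0:
            continue
        gene = dataset.genes[gene_id]
        per_genome.setdefault(gene.genome_id, []).append(copies)
        species.setdefault(gene.genome_id, gene.species)

    rows = []
    for gid in sorted(per_genome):
        counts = per_genome[gid]
        n_prot, n_dom = len(counts), sum(counts)
        rows.append(
            {
                "genome_id": gid,
                "species": species[gid],
                "n_proteins": n_prot,
                "n_domains": n_dom,
                "mean": _round_half_away(Decimal(n_dom) / Decimal(n_prot), 1),
            }
        )
    rows.sort(key=lambda r: (-r["n_domains"], r["genome_id"]))
    table = pd.DataFrame(
        rows, columns=["genome_id", "species", "n_proteins", "n_domains", "mean"]
    )
    n_genomes = len(rows)
    total_dom = int(table["n_domains"].sum()) if n_genomes else 0
    mean = (
        _round_half_away(Decimal(total_dom) / Decimal(n_genomes), 1) if n_genomes else 0.0
    )
    return CopyNumberSummary(table, mean, n_genomes)


@dataclass(frozen=True)
class TaxonomySummary:
    kingdom: FrequencyTable  # domain copies per kingdom
    phylum: FrequencyTable  # domain copies per phylum
    n_genomes: int  # genomes with >= 1 copy
    genome_phylum: FrequencyTable  # genomes with >= 1 copy, per phylum


def taxonomy_table(
    dataset: Dataset,
    target_domain: str,
    cutoff: float = DEFAULT_CUTOFF,
    aliases=None,
) -> TaxonomySummary:
    """Taxonomic rollups of domain copies and of genomes carrying the domain."""
    kingdom_counts: Counter = Counter()
    phylum_counts: Counter = Counter()
    genomes_by_phylum: dict[str, set] = {}
    for gene_id, hits in dataset.hits_by_gene().items():
        surviving = dedupe_hits(apply_aliases(filter_hits(hits, cutoff), aliases))
        copies = sum(1 for h in surviving if h.domain == target_domain)
        if copies == 0:
            continue
        gene = dataset.genes[gene_id]
        kingdom_counts[gene.kingdom or "unknown"] += copies
        phylum_counts[gene.phylum or "unknown"] += copies
        genomes_by_phylum.setdefault(gene.phylum or "unknown", set()).add(gene.genome_id)

    if not phylum_counts:
        raise PulcensusError("empty census")
    genome_counts = {p: len(gs) for p, gs in genomes_by_phylum.items()}
    return TaxonomySummary(
        kingdom=frequency_table(dict(kingdom_counts)),
        phylum=frequency_table(dict(phylum_counts)),
        n_genomes=len(set().union(*genomes_by_phylum.values())),
        genome_phylum=frequency_table(genome_counts),
    )


def write_table(df: pd.DataFrame, path, params: Optional[dict] = None) -> None:
    """Write a TSV with a ``#``-comment provenance header recording parameters."""
    with open(path, "w") as fh:
        if params:
            for k, v in params.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
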