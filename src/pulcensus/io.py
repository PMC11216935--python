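"""Reading and writing gene / domain-hit tables, KEGG flat entries and FASTA.

The central containers are :class:`GeneRecord`, :class:`DomainHit` and
:class:`Dataset`.  Gene identifiers follow the KEGG convention
``genome_id<sep>locus_tag`` where the locus tag ends in the numeric gene
index (``bth:BT_3987`` -> genome ``bth``, index 3987).  Both ``:`` and ``_``
separators are accepted on read; ``:`` is canonical on write.

Optional fields (KO accession, sequence) are ``None`` when absent — never
empty strings — and serialize to empty TSV cells.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    FormatError,
    IntegrityError,
    LookupError_,
)

logger = logging.getLogger(__name__)

#: columns a gene table must provide
MANDATORY_GENE_COLUMNS = (
    "gene_id",
    "genome_id",
    "gene_index",
    "name",
    "annotation",
    "phylum",
)

#: full canonical column order for gene-table writes
GENE_COLUMNS = (
    "gene_id",
    "genome_id",
    "gene_index",
    "name",
    "ko",
    "annotation",
    "kingdom",
    "phylum",
    "species",
    "protein_length",
    "sequence",
)

HIT_COLUMNS = ("gene_id", "domain", "start", "end", "evalue", "source")

_TRAILING_DIGITS = re.compile(r"(\d+)\s*$")


def parse_gene_index(locus_tag: str) -> int:
    """Extract the numeric gene index as the longest trailing digit run.

    Handles ``BT_3987`` -> 3987, ``BACOVA_02653`` -> 2653, ``00150`` -> 150.
    """
    m = _TRAILING_DIGITS.search(str(locus_tag).strip())
    if m is None:
        raise FormatError(f"no numeric tail in locus tag {locus_tag!r}")
    return int(m.group(1))


def split_gene_id(gene_id: str) -> tuple[str, str]:
    """Split ``genome<sep>tag`` on the first ``:`` (preferred) or ``_``."""
    if ":" in gene_id:
        genome, tag = gene_id.split(":", 1)
    elif "_" in gene_id:
        genome, tag = gene_id.split("_", 1)
    else:
        raise FormatError(f"gene id {gene_id!r} has no ':' or '_' separator")
    if not genome or not tag:
        raise FormatError(f"gene id {gene_id!r} has an empty component")
    return genome, tag


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: identity, taxonomy and optional sequence."""

    gene_id: str
    genome_id: str
    gene_index: int
    name: str = ""
    ko: Optional[str] = None
    annotation: str = ""
    kingdom: str = ""
    phylum: str = ""
    species: str = ""
    protein_length: int = 0
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.gene_index < 0:
            raise IntegrityError(f"{self.gene_id}: negative gene_index")
        if self.sequence is not None and self.protein_length:
            if len(self.sequence) != self.protein_length:
                raise IntegrityError(
                    f"{self.gene_id}: declared length {self.protein_length} != "
                    f"sequence length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein, 1-based inclusive aa coordinates.

    ``start``/``end``/``evalue`` may be ``None`` for annotation-only hits
    (e.g. a KEGG MOTIF line); coordinate-requiring operations reject those
    explicitly rather than guessing.
    """

    gene_id: str
    domain: str
    start: Optional[int] = None
    end: Optional[int] = None
    evalue: Optional[float] = None
    source: str = ""

    def __post_init__(self):
        if (self.start is None) != (self.end is None):
            raise IntegrityError(f"{self.gene_id}/{self.domain}: half-open coordinates")
        if self.start is not None:
            if self.start < 1 or self.end < self.start:
                raise IntegrityError(
                    f"{self.gene_id}/{self.domain}: bad interval {self.start}-{self.end}"
                )
        if self.evalue is not None and self.evalue < 0:
            raise IntegrityError(f"{self.gene_id}/{self.domain}: negative E-value")

    @property
    def length(self) -> int:
        if self.start is None:
            raise IntegrityError(f"{self.gene_id}/{self.domain}: no coordinates")
        return self.end - self.start + 1


@dataclass
class Dataset:
    """Genes keyed by gene_id plus their domain hits."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    hits: list[DomainHit] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        unresolved = {h.gene_id for h in self.hits} - self.genes.keys()
        if unresolved:
            raise IntegrityError(
                f"hits reference unknown genes: {', '.join(sorted(unresolved)[:5])}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise LookupError_(f"unknown gene {gene_id!r}") from None

    def hits_for(self, gene_id: str) -> list[DomainHit]:
        return [h for h in self.hits if h.gene_id == gene_id]

    def hits_by_gene(self) -> dict[str, list[DomainHit]]:
        out: dict[str, list[DomainHit]] = {g: [] for g in self.genes}
        for h in self.hits:
            out[h.gene_id].append(h)
        return out

    def genome_ids(self) -> list[str]:
        return sorted({g.genome_id for g in self.genes.values()})

    def genes_in_genome(self, genome_id: str) -> list[GeneRecord]:
        """Genes of one genome sorted by gene index."""
        recs = [g for g in self.genes.values() if g.genome_id == genome_id]
        return sorted(recs, key=lambda g: g.gene_index)


# ---------------------------------------------------------------------------
# TSV tables


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing mandatory column(s): {', '.join(missing)}")


def parse_gene_table(path, hits_path=None, provenance: str = "") -> Dataset:
    """Read a TSV gene table (and optionally a domain-hit table) into a Dataset.

    Blank ``ko``/``sequence`` cells become ``None``.  ``gene_index`` may be a
    bare number or a full locus tag; the numeric tail is used either way.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    _require_columns(df, MANDATORY_GENE_COLUMNS, f"gene table {path.name}")

    dupes = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if dupes:
        raise DuplicateIdError(dupes)

    genes: dict[str, GeneRecord] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        seq = d.get("sequence", "") or None
        length = d.get("protein_length", "")
        genes[d["gene_id"]] = GeneRecord(
            gene_id=d["gene_id"],
            genome_id=d["genome_id"],
            gene_index=parse_gene_index(d["gene_index"]),
            name=d.get("name", ""),
            ko=d.get("ko", "") or None,
            annotation=d.get("annotation", ""),
            kingdom=d.get("kingdom", ""),
            phylum=d.get("phylum", ""),
            species=d.get("species", ""),
            protein_length=int(length) if length else (len(seq) if seq else 0),
            sequence=seq,
        )

    hits: list[DomainHit] = []
    if hits_path is not None:
        hits = parse_hit_table(hits_path)
    return Dataset(genes=genes, hits=hits, provenance=provenance or str(path))


def parse_hit_table(path) -> list[DomainHit]:
    """Read a TSV domain-hit table (gene_id, domain, start, end, evalue, source)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    _require_columns(df, ("gene_id", "domain"), f"hit table {path.name}")
    hits = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        start = d.get("start", "")
        end = d.get("end", "")
        ev = d.get("evalue", "")
        hits.append(
            DomainHit(
                gene_id=d["gene_id"],
                domain=d["domain"].strip(),
                start=int(float(start)) if start else None,
                end=int(float(end)) if end else None,
                evalue=float(ev) if ev else None,
                source=d.get("source", ""),
            )
        )
    return hits


def write_gene_table(dataset: Dataset, path) -> int:
    """Write the gene table as TSV; absent optionals become empty cells."""
    rows = []
    for g in sorted(dataset.genes.values(), key=lambda g: (g.genome_id, g.gene_index)):
        rows.append(
            {
                "gene_id": g.gene_id,
                "genome_id": g.genome_id,
                "gene_index": g.gene_index,
                "name": g.name,
                "ko": g.ko or "",
                "annotation": g.annotation,
                "kingdom": g.kingdom,
                "phylum": g.phylum,
                "species": g.species,
                "protein_length": g.protein_length,
                "sequence": g.sequence or "",
            }
        )
    pd.DataFrame(rows, columns=list(GENE_COLUMNS)).to_csv(path, sep="\t", index=False)
    return len(rows)


def write_hit_table(hits: Sequence[DomainHit], path) -> int:
    rows = [
        {
            "gene_id": h.gene_id,
            "domain": h.domain,
            "start": "" if h.start is None else h.start,
            "end": "" if h.end is None else h.end,
            "evalue": "" if h.evalue is None else repr(h.evalue),
            "source": h.source,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=list(HIT_COLUMNS)).to_csv(path, sep="\t", index=False)
    return len(rows)


# ---------------------------------------------------------------------------
# KEGG flat entries

_KEGG_FIELD = re.compile(r"^([A-Z_]+)\s+(.*)$")


def parse_kegg_flatfile(text: str, genome_id: Optional[str] = None):
    """Parse one KEGG-style flat gene entry into (GeneRecord, [DomainHit]).

    Recognised blocks: ENTRY, NAME, ORTHOLOGY, ORGANISM, MOTIF, AASEQ.
    MOTIF domains carry no coordinates at this stage; a coordinate-bearing
    hit table, when available, supersedes them.
    """
    blocks: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        if line.strip() == "///":
            break
        m = _KEGG_FIELD.match(line)
        if m:
            current = m.group(1)
            blocks.setdefault(current, []).append(m.group(2).strip())
        elif current and line.startswith(" "):
            blocks[current].append(line.strip())

    if "ENTRY" not in blocks:
        raise FormatError("no ENTRY line in KEGG flat entry")

    entry_tokens = blocks["ENTRY"][0].split()
    locus_tag = entry_tokens[0]
    name = "; ".join(blocks.get("NAME", [])).strip()

    ko = None
    annotation = name
    if "ORTHOLOGY" in blocks:
        first = blocks["ORTHOLOGY"][0]
        parts = first.split(None, 1)
        if parts and re.fullmatch(r"K\d{5}", parts[0]):
            ko = parts[0]
            if len(parts) > 1:
                annotation = parts[1]

    organism = " ".join(blocks.get("ORGANISM", []))
    org_tokens = organism.split(None, 1)
    org_code = org_tokens[0] if org_tokens else ""
    species = org_tokens[1] if len(org_tokens) > 1 else ""
    genome = genome_id or org_code or "unknown"

    sequence = None
    declared_len = 0
    if "AASEQ" in blocks:
        aaseq = blocks["AASEQ"]
        try:
            declared_len = int(aaseq[0].split()[0])
        except (ValueError, IndexError):
            raise FormatError(f"unparseable AASEQ length line: {aaseq[0]!r}")
        sequence = "".join(aaseq[1:]).replace(" ", "").upper()
        if len(sequence) != declared_len:
            raise IntegrityError(
                f"{locus_tag}: AASEQ declares {declared_len} aa but sequence "
                f"has {len(sequence)}"
            )

    gene_id = f"{genome}:{locus_tag}"
    record = GeneRecord(
        gene_id=gene_id,
        genome_id=genome,
        gene_index=parse_gene_index(locus_tag),
        name=name,
        ko=ko,
        annotation=annotation,
        species=species,
        protein_length=declared_len or (len(sequence) if sequence else 0),
        sequence=sequence,
    )

    hits = []
    for chunk in blocks.get("MOTIF", []):
        # layout: "Pfam: DUF1735 Laminin_G_3" or a bare domain list
        chunk = re.sub(r"^[A-Za-z0-9_-]+:\s*", "", chunk)
        for dom in chunk.split():
            hits.append(DomainHit(gene_id=gene_id, domain=dom, source="kegg-motif"))
    return record, hits


# ---------------------------------------------------------------------------
# FASTA

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def write_fasta(records: Iterable[GeneRecord], path) -> int:
    """Write sequences as FASTA (``>gene_id annotation``, 60-col wrap).

    Records without a sequence are skipped with a warning and excluded from
    the returned count.
    """
    out = []
    for rec in records:
        if rec.sequence is None:
            logger.warning("skipping %s: no sequence", rec.gene_id)
            continue
        out.append(
            SeqRecord(Seq(rec.sequence), id=rec.gene_id, description=rec.annotation)
        )
    return SeqIO.write(out, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA back as {id: sequence} (round-trip checks, signalp input)."""
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# signalp-style tabular output (prediction done elsewhere; we only parse)


def parse_signalp_table(path) -> dict[str, str]:
    """Parse a signalp6-like tab-separated output into {id: predicted class}.

    Comment lines (#) are skipped; only the first two columns are read.
    """
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            parts = line.split()
        if len(parts) >= 2:
            out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# pluggable backend contract


class Backend:
    """Minimal fetch contract: map a domain name to gene ids, an id to an entry.

    The offline :class:`FixtureBackend` is the default and the only backend
    exercised by tests; a live REST adapter can implement the same two calls.
    """

    def find_genes(self, domain: str) -> list[str]:  # pragma: no cover - contract
        raise NotImplementedError

    def get_entry(self, gene_id: str) -> str:  # pragma: no cover - contract
        raise NotImplementedError


class FixtureBackend(Backend):
    """Serve KEGG flat entries from an in-memory mapping or a directory."""

    def __init__(self, entries: Mapping[str, str], domain_index: Mapping[str, list[str]]):
        self._entries = dict(entries)
        self._index = {k: list(v) for k, v in domain_index.items()}

    def find_genes(self, domain: str) -> list[str]:
        return list(self._index.get(domain, []))

    def get_entry(self, gene_id: str) -> str:
        try:
            return self._entries[gene_id]
        except KeyError:
            raise LookupError_(f"fixture backend has no entry for {gene_id!r}") from None
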