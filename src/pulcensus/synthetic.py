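"""Synthetic KEGG-like genomes with planted, manifest-backed ground truth.

The generator emulates the statistical quirks of real KEGG gene tables that
the scanner must survive: locus-tag numbering in steps of 1, 5 or 10 with
occasional gaps; susC/susD marker pairs with a target-domain gene one to
three genes downstream; SusD evidence split across a KO accession, domain
annotations and free-text names; E-values straddling the census cutoff; and
DUF1735/DUF4973-style overlapping domain calls.

Planting is exact, not sampled: requested fractions (evidence-tier mix,
downstream-position mix, overlap-pair rate) are realized by largest-remainder
counting, so tests against the manifest are equalities rather than
statistical checks.  Taxonomy names are fictional and marked synthetic.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from .errors import ConfigError
from .io import Dataset, DomainHit, GeneRecord
from .vicinity import TIER_D, TIER_ID, TIER_N

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: domain E-value cutoff the planted truth is expressed against
CUTOFF = 1e-4

_POSITION_BY_DISTANCE = {1: "susE-like", 2: "susF-like", 3: "susG-like"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the structure of the real census data: a Bacteroidota-
    dominated set of bacterial genomes, numbering steps drawn evenly from
    {1, 5, 10}, a 98% target-in-PUL rate (49 planted loci, 1 decoy), 14% of
    marker genes identifiable only by the SusD KO, and a 47/35/18 split of
    targets over the susE/susF/susG-like downstream slots.
    """

    n_genomes: int = 20
    genes_per_genome: int = 120
    step_choices: tuple[int, ...] = (1, 5, 10)
    gap_rate: float = 0.05
    n_planted: int = 49
    n_decoys: int = 1
    window: int = 5
    target_domain: str = "DUF1735"
    #: signed rank offset of the susD gene relative to the target; negative
    #: means the target sits downstream of the susC/susD pair
    offset_weights: dict = field(
        default_factory=lambda: {-1: 0.47, -2: 0.35, -3: 0.18}
    )
    tier_weights: dict = field(
        default_factory=lambda: {TIER_ID: 0.14, TIER_D: 0.66, TIER_N: 0.20}
    )
    overlap_pair_rate: float = 0.30
    #: C-terminal partner mix for target proteins (None = single-domain)
    cterm_weights: dict = field(
        default_factory=lambda: {
            "LamG3": 0.21,
            "DUF4361": 0.19,
            None: 0.16,
            "DUF1735": 0.16,
            "F5/8-typeC": 0.12,
            "DUF5627": 0.10,
            "GH18": 0.06,
        }
    )
    phylum_weights: dict = field(
        default_factory=lambda: {
            "Bacteroidota-like (synthetic)": 0.87,
            "Pseudomonadota-like (synthetic)": 0.13,
        }
    )
    with_sequences: bool = True


@dataclass(frozen=True)
class GenomeTruth:
    genome_id: str
    step: int
    n_genes: int
    gap_ranks: tuple[int, ...]
    phylum: str
    species: str


@dataclass(frozen=True)
class HitTruth:
    domain: str
    start: int
    end: int
    evalue: float
    survives: bool  # True iff evalue <= cutoff


@dataclass(frozen=True)
class PlantedLocus:
    target_gene_id: str
    susc_gene_id: str
    susd_gene_id: str
    offset: int  # signed rank offset of susD from the target
    tier: str
    position_class: str
    expected_label: str
    n_domain_copies: int


@dataclass
class SyntheticManifest:
    """Everything needed to predict the outputs of scan/architecture/summarize."""

    seed: int
    window: int
    target_domain: str
    genomes: list[GenomeTruth] = field(default_factory=list)
    planted: list[PlantedLocus] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)
    domain_truth: dict[str, list[HitTruth]] = field(default_factory=dict)

    @property
    def pul_positive_fraction(self) -> float:
        n = len(self.planted) + len(self.decoys)
        return len(self.planted) / n if n else 0.0

    def tier_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.planted:
            out[p.tier] = out.get(p.tier, 0) + 1
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "window": self.window,
                "target_domain": self.target_domain,
                "genomes": [asdict(g) for g in self.genomes],
                "planted": [asdict(p) for p in self.planted],
                "decoys": self.decoys,
                "domain_truth": {
                    g: [asdict(h) for h in hs] for g, hs in self.domain_truth.items()
                },
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticManifest":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            window=d["window"],
            target_domain=d["target_domain"],
            genomes=[
                GenomeTruth(**{**g, "gap_ranks": tuple(g["gap_ranks"])})
                for g in d["genomes"]
            ],
            planted=[PlantedLocus(**p) for p in d["planted"]],
            decoys=list(d["decoys"]),
            domain_truth={
                g: [HitTruth(**h) for h in hs] for g, hs in d["domain_truth"].items()
            },
        )


def exact_counts(total: int, weights: dict) -> dict:
    """Apportion ``total`` over keys proportionally via largest remainder."""
    if total < 0:
        raise ConfigError("total must be >= 0")
    wsum = sum(weights.values())
    if wsum <= 0:
        raise ConfigError("weights must sum to a positive value")
    raw = {k: total * w / wsum for k, w in weights.items()}
    out = {k: int(v) for k, v in raw.items()}
    short = total - sum(out.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - out[k]), str(k)))[:short]:
        out[k] += 1
    return out


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA_LETTERS) for _ in range(length))


def _filler_gene(gene_id, genome_id, index, phylum, species, rng, with_seq):
    length = rng.randrange(120, 420)
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome_id,
        gene_index=index,
        name=f"fg{index}",
        annotation="hypothetical protein",
        kingdom="Bacteria",
        phylum=phylum,
        species=species,
        protein_length=length,
        sequence=_random_seq(rng, length) if with_seq else None,
    )


# domain layout templates for planted target proteins ----------------------

_CTERM_COORDS = {
    "LamG3": (170, 340),
    "DUF4361": (170, 320),
    "F5/8-typeC": (170, 310),
    "DUF5627": (170, 300),
    "GH18": (170, 460),
    "DUF1735": (170, 285),
}
_PRIMARY_COORDS = (25, 140)
_OVERLAP_COORDS = (30, 145)  # DUF4973 riding on the primary domain


def _target_hit_truths(
    rng: random.Random, target: str, cterm: Optional[str], with_overlap: bool
) -> list[HitTruth]:
    hits = [
        HitTruth(target, *_PRIMARY_COORDS, evalue=10 ** rng.uniform(-30, -6), survives=True)
    ]
    if with_overlap:
        hits.append(
            HitTruth("DUF4973", *_OVERLAP_COORDS, evalue=10 ** rng.uniform(-20, -5),
                     survives=True)
        )
    if cterm is not None:
        hits.append(
            HitTruth(cterm, *_CTERM_COORDS[cterm], evalue=10 ** rng.uniform(-25, -5),
                     survives=True)
        )
    # noise straddling the cutoff: one failing hit, and a boundary-E duplicate
    # of the primary call that the deduper must fold away
    end = max(h.end for h in hits)
    hits.append(
        HitTruth("DUF9999", end + 20, end + 120,
                 evalue=10 ** rng.uniform(-3.5, -1.5), survives=False)
    )
    if rng.random() < 0.5:
        hits.append(HitTruth(target, *_PRIMARY_COORDS, evalue=CUTOFF, survives=True))
    return hits


def _expected_label(target: str, cterm: Optional[str], with_overlap: bool) -> str:
    head = f"{target}*" if with_overlap else target
    return head if cterm is None else f"{head} + {cterm}"


def _susd_gene(gene_id, genome_id, index, tier, phylum, species, rng, with_seq):
    """Marker gene whose SusD evidence sits exactly at the requested tier."""
    ko = None
    name, annotation = "mg", "hypothetical protein"
    hits: list[DomainHit] = []
    if tier == TIER_ID:
        ko = "K21572"
    elif tier == TIER_D:
        dom = rng.choice(["SusD-like domain", "RagB"])
        hits = [DomainHit(gene_id, dom, 30, 480, 10 ** rng.uniform(-40, -8), "synthetic")]
    elif tier == TIER_N:
        annotation = rng.choice(
            ["RagB/SusD family nutrient uptake protein", "SusD family protein"]
        )
    else:
        raise ConfigError(f"unknown tier {tier!r}")
    length = 520
    rec = GeneRecord(
        gene_id=gene_id,
        genome_id=genome_id,
        gene_index=index,
        name=name,
        ko=ko,
        annotation=annotation,
        kingdom="Bacteria",
        phylum=phylum,
        species=species,
        protein_length=length,
        sequence=_random_seq(rng, length) if with_seq else None,
    )
    return rec, hits


def generate(
    config: GeneratorConfig = GeneratorConfig(), seed: int = 0
) -> tuple[Dataset, SyntheticManifest]:
    """Build a Dataset plus the manifest that fully determines expected outputs.

    Deterministic for a given (config, seed); two calls produce identical
    objects and therefore byte-identical table writes.
    """
    rng = random.Random(seed)
    w = config.window

    # capacity check: each locus claims a block of 2w+6 gene slots so that
    # scan windows of distinct loci never touch
    stride = 2 * w + 6
    per_genome_slots = config.genes_per_genome // stride
    n_loci = config.n_planted + config.n_decoys
    if n_loci > per_genome_slots * config.n_genomes:
        raise ConfigError(
            f"{n_loci} loci do not fit: {config.n_genomes} genomes x "
            f"{per_genome_slots} blocks of {stride} genes"
        )

    # exact apportionments ------------------------------------------------
    tier_alloc = exact_counts(config.n_planted, config.tier_weights)
    offset_alloc = exact_counts(config.n_planted, config.offset_weights)
    n_overlap = exact_counts(
        config.n_planted, {"yes": config.overlap_pair_rate,
                           "no": 1 - config.overlap_pair_rate}
    )["yes"]
    cterm_alloc = exact_counts(config.n_planted, config.cterm_weights)
    phylum_alloc = exact_counts(config.n_genomes, config.phylum_weights)

    tiers = [t for t, c in tier_alloc.items() for _ in range(c)]
    offsets = [int(o) for o, c in offset_alloc.items() for _ in range(c)]
    overlaps = [True] * n_overlap + [False] * (config.n_planted - n_overlap)
    cterms = [ct for ct, c in cterm_alloc.items() for _ in range(c)]
    phyla = [p for p, c in phylum_alloc.items() for _ in range(c)]
    for lst in (tiers, offsets, overlaps, cterms, phyla):
        rng.shuffle(lst)

    genes: dict[str, GeneRecord] = {}
    hits: list[DomainHit] = []
    manifest = SyntheticManifest(
        seed=seed, window=w, target_domain=config.target_domain
    )

    # locus slots: (genome serial, block rank) round-robin over genomes
    slots = [
        (gi, b) for b in range(per_genome_slots) for gi in range(config.n_genomes)
    ][:n_loci]
    locus_kind = ["planted"] * config.n_planted + ["decoy"] * config.n_decoys
    rng.shuffle(locus_kind)
    loci_by_genome: dict[int, list[tuple[int, str]]] = {}
    for (gi, block), kind in zip(slots, locus_kind):
        loci_by_genome.setdefault(gi, []).append((block, kind))

    planted_iter = iter(range(config.n_planted))

    for gi in range(config.n_genomes):
        genome_id = f"sg{gi:02d}"
        step = rng.choice(config.step_choices)
        phylum = phyla[gi]
        species = f"Fictibacter syntheticus {gi + 1} (synthetic)"

        # indices with occasional gaps (a skipped slot doubles the increment)
        indices: list[int] = []
        nxt = step
        gap_ranks: list[int] = []
        for rank in range(config.genes_per_genome):
            if rank > 0 and rng.random() < config.gap_rate:
                nxt += step
                gap_ranks.append(rank)
            indices.append(nxt)
            nxt += step

        def gid(rank: int) -> str:
            return f"{genome_id}:{indices[rank]:05d}"

        special: dict[int, tuple[str, object]] = {}  # rank -> (role, payload)
        for block, kind in loci_by_genome.get(gi, []):
            base = block * stride + w + 1  # rank of the target gene
            if kind == "decoy":
                special[base] = ("decoy", None)
                continue
            k = next(planted_iter)
            offset = offsets[k]
            r_susd = base + offset
            r_susc = r_susd - 1 if offset < 0 else r_susd + 1  # far side of pair
            special[base] = (
                "target",
                {"tier": tiers[k], "offset": offset, "overlap": overlaps[k],
                 "cterm": cterms[k], "susd_rank": r_susd, "susc_rank": r_susc},
            )
            special[r_susd] = ("susd", tiers[k])
            special[r_susc] = ("susc", None)

        for rank in range(config.genes_per_genome):
            gene_id = gid(rank)
            role, payload = special.get(rank, ("filler", None))
            if role == "susd":
                rec, dh = _susd_gene(
                    gene_id, genome_id, indices[rank], payload, phylum, species,
                    rng, config.with_sequences,
                )
                genes[gene_id] = rec
                hits.extend(dh)
            elif role == "susc":
                length = 760
                genes[gene_id] = GeneRecord(
                    gene_id=gene_id, genome_id=genome_id, gene_index=indices[rank],
                    name="susC", ko="K21573",
                    annotation="SusC-like TonB-dependent transporter",
                    kingdom="Bacteria", phylum=phylum, species=species,
                    protein_length=length,
                    sequence=_random_seq(rng, length) if config.with_sequences else None,
                )
            elif role in ("target", "decoy"):
                if role == "target":
                    truths = _target_hit_truths(
                        rng, config.target_domain, payload["cterm"], payload["overlap"]
                    )
                else:
                    truths = [
                        HitTruth(config.target_domain, *_PRIMARY_COORDS,
                                 evalue=10 ** rng.uniform(-30, -6), survives=True)
                    ]
                length = max(h.end for h in truths) + rng.randrange(10, 40)
                genes[gene_id] = GeneRecord(
                    gene_id=gene_id, genome_id=genome_id, gene_index=indices[rank],
                    name=f"tp{indices[rank]}",
                    annotation="protein of unknown function",
                    kingdom="Bacteria", phylum=phylum, species=species,
                    protein_length=length,
                    sequence=_random_seq(rng, length) if config.with_sequences else None,
                )
                hits.extend(
                    DomainHit(gene_id, h.domain, h.start, h.end, h.evalue, "synthetic")
                    for h in truths
                )
                manifest.domain_truth[gene_id] = truths
                if role == "decoy":
                    manifest.decoys.append(gene_id)
                else:
                    # the boundary-E duplicate collapses in deduplication
                    dedup = {(h.domain, h.start, h.end)
                             for h in truths
                             if h.domain == config.target_domain and h.survives}
                    manifest.planted.append(
                        PlantedLocus(
                            target_gene_id=gene_id,
                            susc_gene_id=gid(payload["susc_rank"]),
                            susd_gene_id=gid(payload["susd_rank"]),
                            offset=payload["offset"],
                            tier=payload["tier"],
                            position_class=_POSITION_BY_DISTANCE[
                                abs(payload["offset"])
                            ],
                            expected_label=_expected_label(
                                config.target_domain, payload["cterm"],
                                payload["overlap"],
                            ),
                            n_domain_copies=len(dedup),
                        )
                    )
            else:
                genes[gene_id] = _filler_gene(
                    gene_id, genome_id, indices[rank], phylum, species, rng,
                    config.with_sequences,
                )

        manifest.genomes.append(
            GenomeTruth(genome_id, step, config.genes_per_genome,
                        tuple(gap_ranks), phylum, species)
        )

    dataset = Dataset(genes=genes, hits=hits, provenance=f"synthetic(seed={seed})")
    _verify_decoys(dataset, manifest)
    return dataset, manifest


def _verify_decoys(dataset: Dataset, manifest: SyntheticManifest) -> None:
    """Brute-force check that no decoy has a marker gene within the window."""
    susd_ids = {p.susd_gene_id for p in manifest.planted}
    for decoy in manifest.decoys:
        genome = dataset.gene(decoy).genome_id
        ordered = [g.gene_id for g in dataset.genes_in_genome(genome)]
        r = ordered.index(decoy)
        window = ordered[max(0, r - manifest.window): r + manifest.window + 1]
        if susd_ids & set(window):
            raise ConfigError(f"decoy {decoy} has a planted marker in its window")


@dataclass
class ExpectedScan:
    """Brute-force prediction of what vicinity.scan must report."""

    n_targets: int
    n_pul_positive: int
    tier_counts: dict[str, int]
    positives: dict[str, tuple[str, str, int]]  # target -> (susd id, tier, offset)

    @property
    def fraction(self) -> float:
        return self.n_pul_positive / self.n_targets if self.n_targets else 0.0


def expected_scan(dataset: Dataset, manifest: SyntheticManifest, w: int) -> ExpectedScan:
    """Predict the scan outcome by direct sort-rank-window enumeration.

    Marker genes and their tiers are read from the manifest (planted truth),
    never re-derived from annotations, so this is an independent oracle for
    the scanner.
    """
    marker = {p.susd_gene_id: p.tier for p in manifest.planted}
    tier_rank = {TIER_ID: 0, TIER_D: 1, TIER_N: 2}
    targets = [p.target_gene_id for p in manifest.planted] + list(manifest.decoys)

    positives: dict[str, tuple[str, str, int]] = {}
    tier_counts: dict[str, int] = {}
    for t in sorted(targets):
        genome = dataset.gene(t).genome_id
        ordered = [g.gene_id for g in dataset.genes_in_genome(genome)]
        r = ordered.index(t)
        best = None
        for off in range(-w, w + 1):
            if off == 0 or not 0 <= r + off < len(ordered):
                continue
            nid = ordered[r + off]
            if nid in marker:
                key = (tier_rank[marker[nid]], abs(off), 0 if off < 0 else 1)
                if best is None or key < best[0]:
                    best = (key, nid, marker[nid], off)
        if best is not None:
            positives[t] = (best[1], best[2], best[3])
            tier_counts[best[2]] = tier_counts.get(best[2], 0) + 1

    return ExpectedScan(
        n_targets=len(targets),
        n_pul_positive=len(positives),
        tier_counts=tier_counts,
        positives=positives,
    )
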