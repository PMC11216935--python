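import pytest
from hypothesis import settings

from pulcensus.io import Dataset, DomainHit, GeneRecord

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


def make_gene(gene_id="g01:00010", index=None, **kw):
    genome, tag = gene_id.split(":")
    defaults = dict(
        gene_id=gene_id,
        genome_id=genome,
        gene_index=index if index is not None else int(tag),
        name="gene",
        annotation="hypothetical protein",
        kingdom="Bacteria",
        phylum="Bacteroidota-like (synthetic)",
        species="Fictibacter syntheticus (synthetic)",
        protein_length=400,
    )
    defaults.update(kw)
    return GeneRecord(**defaults)


@pytest.fixture
def small_dataset():
    """One regular step-10 genome of 11 genes; a susD one gene upstream of
    a DUF1735 gene, susC on the far side of susD."""
    genes = {}
    for i in range(1, 12):
        gid = f"g01:{i * 10:05d}"
        genes[gid] = make_gene(gid)
    susc = "g01:00040"
    susd = "g01:00050"
    target = "g01:00060"
    genes[susc] = make_gene(susc, ko="K21573",
                            annotation="SusC-like TonB-dependent transporter")
    genes[susd] = make_gene(susd, ko="K21572")
    hits = [
        DomainHit(target, "DUF1735", 25, 140, 1e-9, "synthetic"),
        DomainHit(target, "LamG3", 170, 340, 1e-8, "synthetic"),
    ]
    return Dataset(genes=genes, hits=hits, provenance="fixture"), target, susd, susc
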