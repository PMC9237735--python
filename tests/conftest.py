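import pytest

from isostack import GenomicInterval, ReadIsoform, default_truth, simulate_reads


def make_read(read_id, exon_pairs, chrom="chrT", cell_type="A", gene_id="G",
              tss=None, polya=None, strand="+"):
    """Terse read builder for unit tests: exon_pairs are (start, end) tuples."""
    return ReadIsoform(
        read_id=read_id,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs],
        gene_id=gene_id,
        cell_type=cell_type,
        tss=tss,
        polya=polya,
    )


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=0)


@pytest.fixture(scope="session")
def dataset(truth, tmp_path_factory):
    """The standard simulated dataset, written once in every dialect."""
    outdir = tmp_path_factory.mktemp("fixture")
    return simulate_reads(truth, seed=1, outdir=outdir)
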