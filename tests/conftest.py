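import pytest

from deuteromics import OrfRecord, OrfTable


def make_record(orf_id, taxon="Bacteria;P;C;O;F;G;Species_1", gene_name="",
                annotations=None, length_bp=300, has_start=True, has_stop=True,
                gc_fraction=0.5, tpm=None):
    return OrfRecord(
        orf_id=orf_id, contig_id="contig_1", taxon=taxon, gene_name=gene_name,
        annotations=set(annotations or ()), length_bp=length_bp,
        has_start=has_start, has_stop=has_stop, gc_fraction=gc_fraction,
        tpm=dict(tpm or {}))


@pytest.fixture
def small_table():
    """Three ORFs over two samples, mixed taxa and annotations."""
    records = [
        make_record("orf1", taxon="B;P;C;O;F;G;Species_1", gene_name="recA",
                    annotations={"K03553"}, length_bp=300,
                    tpm={"S1": 100.0, "S2": 50.0}),
        make_record("orf2", taxon="B;P;C;O;F;G;Species_2",
                    gene_name="transposase", annotations={"COG2801"},
                    length_bp=900, tpm={"S1": 300.0, "S2": 0.0}),
        make_record("orf3", taxon="B;P;C;O;F;G;unknown_7", length_bp=600,
                    tpm={"S1": 0.0, "S2": 150.0}),
    ]
    return OrfTable(records, ["S1", "S2"])
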