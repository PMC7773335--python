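import pytest

from repseq_subsets.features import load_property_table
from repseq_subsets.io import Clonotype, Repertoire
from repseq_subsets.normalization import recompute_frequencies


@pytest.fixture(scope="session")
def prop_table():
    return load_property_table()


def make_clonotype(count=1, cdr3nt="TGTGCCAGCAGCTTC", cdr3aa="CASSF",
                   v="TRBV-sim-01", d="TRBD-sim-01", j="TRBJ-sim-01",
                   v_end=3, d_start=6, d_end=9, j_start=12, freq=0.0):
    return Clonotype(count=count, freq=freq, cdr3nt=cdr3nt, cdr3aa=cdr3aa,
                     v_gene=v, d_gene=d, j_gene=j,
                     v_end=v_end, d_start=d_start, d_end=d_end, j_start=j_start)


def make_repertoire(counts, donor="D1", subset="Tfh", chain="TRB", seqs=None):
    """Repertoire with given counts; distinct CDR3nt per clonotype."""
    clonotypes = []
    for i, n in enumerate(counts):
        if seqs is not None:
            nt = seqs[i]
        else:
            # unique 13-mer per index (length not divisible by 3 on purpose,
            # so the aa field is not subject to the translation check)
            code = "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(7))
            nt = "TGT" + code + "TTC"
        clonotypes.append(make_clonotype(count=int(n), cdr3nt=nt, cdr3aa="CASSF",
                                         v_end=1, d_start=3, d_end=5,
                                         j_start=min(8, len(nt) - 1)))
    rep = Repertoire(donor_id=donor, subset=subset, chain=chain, clonotypes=clonotypes)
    return recompute_frequencies(rep)


@pytest.fixture
def toy_repertoire():
    return make_repertoire([6, 3, 1])
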