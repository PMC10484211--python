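import numpy as np
import pytest

from raescan.ase_io import AlleleCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(X, N, genes=None, tissues=None, missing=None, individual_id="IND1",
               sex="unknown"):
    X = np.asarray(X)
    N = np.asarray(N)
    if genes is None:
        genes = [f"g{i}" for i in range(X.shape[0])]
    if tissues is None:
        tissues = [f"t{j}" for j in range(X.shape[1])]
    if missing is None:
        missing = np.zeros(X.shape, dtype=bool)
    return AlleleCountTable(
        individual_id=individual_id,
        sex=sex,
        genes=genes,
        tissues=tissues,
        X=X,
        N=N,
        missing=missing,
    )


@pytest.fixture
def table_factory():
    return make_table


def write_matrix(path, rows, tissues):
    """Write a phASER-style matrix: rows is {gene: [cell, ...]} with cells
    already formatted as 'a|b' strings ('' for missing)."""
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(tissues) + "\n")
        for gene, cells in rows.items():
            fh.write(gene + "\t" + "\t".join(cells) + "\n")
    return path


@pytest.fixture
def matrix_writer(tmp_path):
    def _write(rows, tissues, name="ind.tsv"):
        return write_matrix(tmp_path / name, rows, tissues)

    return _write
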