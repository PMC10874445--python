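import numpy as np
import pytest

from mitodel import refcat


@pytest.fixture(scope="session")
def ref():
    return refcat.default_reference()


@pytest.fixture(scope="session")
def catalog(ref):
    return refcat.default_catalog(ref)


@pytest.fixture()
def toy_ref():
    """Small repeat-free circular genome with tiny benchmark windows."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    return refcat.MitoReference(
        name="toy", sequence=seq, benchmark_windows=((5, 14), (41, 50)), genes=()
    )


@pytest.fixture()
def write_fastq(tmp_path):
    def _write(records, name="reads.fastq"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for i, rec in enumerate(records):
                rid, seq = rec if isinstance(rec, tuple) else (f"r{i}", rec)
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        return path

    return _write
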