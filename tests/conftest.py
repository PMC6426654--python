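import numpy as np
import pytest

import retrotrace as rt


@pytest.fixture(scope="session")
def small_genes():
    """Deterministic 60-gene set used across profiler/locstats tests."""
    return rt.simulate_genes(60, seed=101)


@pytest.fixture(scope="session")
def small_ref(small_genes):
    return rt.build_truncation_set(small_genes, max_missing=13)


@pytest.fixture(scope="session")
def noise_free_sim(small_genes):
    design = rt.default_design(small_genes, seed=7, depth=20_000)
    return rt.simulate_reads(small_genes, design, mode="noise_free")


@pytest.fixture(scope="session")
def noise_free_counts(noise_free_sim, small_ref):
    by_sample = {
        sid: rt.assign_reads(reads, small_ref)
        for sid, reads in noise_free_sim.reads_by_sample.items()
    }
    return rt.count_matrix(by_sample, noise_free_sim.samples, small_ref)


def toy_fasta(tmp_path, records):
    """Write a native-dialect FASTA from (id, aa, anticodon, pseudo, seq)."""
    path = tmp_path / "genes.fa"
    with open(path, "w") as fh:
        for gid, aa, ac, pseudo, seq in records:
            fh.write(f">{gid}|{aa}|{ac}|pseudo={int(pseudo)}\n{seq}\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(0)
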