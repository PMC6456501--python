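import numpy as np
import pandas as pd
import pytest

import scarsig as ss


@pytest.fixture(scope="session")
def genome():
    return ss.toy_genome()


@pytest.fixture(scope="session")
def W10():
    """Ten Dirichlet signatures over the 96 canonical channels."""
    return ss.make_signature_matrix(10, seed=11)


@pytest.fixture(scope="session")
def zero_cutoffs(W10):
    return pd.Series(0.0, index=W10.columns)


@pytest.fixture()
def toy_fasta(tmp_path):
    """Tiny two-chromosome FASTA opened with pyfaidx."""
    import pyfaidx

    path = tmp_path / "toy.fa"
    path.write_text(">chrA\nACGTACGTACGT\n>chrB\nACACACACAC\n>chrC\nACACA\n")
    return pyfaidx.Fasta(str(path))


@pytest.fixture(scope="session")
def scar_events():
    """CN event list whose length-weighted tumor ploidy is exactly 2.20."""
    return (
        ss.CNEvent("chr1", 0, 25_000_000, 2, 0),
        ss.CNEvent("chr2", 40_000_000, 90_000_000, 1, 2),
        ss.CNEvent("chr3", 0, 44_000_000, 1, 2),
        ss.CNEvent("chr3", 80_000_000, 120_000_000, 0, 1),
    )


def random_segment_profile(rng, genome, max_segments=30):
    """Random multi-chromosome integer-state segment profile for oracle tests."""
    rows = []
    for chrom in genome.chromosomes:
        n = int(rng.integers(1, max(2, max_segments // len(genome.chromosomes) + 1)))
        cuts = np.sort(rng.choice(np.arange(1, chrom.length // 1_000_000), size=n - 1,
                                  replace=False)) * 1_000_000 if n > 1 else np.array([], int)
        bounds = np.concatenate([[0], cuts, [chrom.length]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            cn_a = int(rng.integers(0, 3))
            cn_b = int(rng.integers(cn_a, 4))
            if cn_a + cn_b == 0:
                cn_b = 1
            rows.append((chrom.name, int(s), int(e), cn_a + cn_b, cn_a, cn_b))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tcn", "cn_a", "cn_b"])
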