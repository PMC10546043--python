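import numpy as np
import pytest

import fmlseq as f


def make_palindrome_genome(length: int = 200, center: int = 100) -> dict[str, str]:
    """All-A sequence with one YNCGNR palindrome; forward mC at `center`."""
    seq = ["A"] * length
    for i, b in zip(range(center - 2, center + 4), "TACGAG"):
        seq[i] = b
    return {"chrP": "".join(seq)}


@pytest.fixture(scope="session")
def palindrome_genome():
    return make_palindrome_genome()


@pytest.fixture(scope="session")
def random_genome():
    return f.generate_genome(20_000, cpg_enrichment=0.5, seed=7)


@pytest.fixture(scope="session")
def random_sites(random_genome):
    return f.scan_motifs(random_genome, pattern="CGNR")


def complete_digestion(genome, sites, n_copies=1, seed=0, **cfg_kw):
    """Fully methylated profile digested with probability 1."""
    profile = f.generate_profile(sites, mode="all_methylated")
    cfg = f.SimConfig(n_copies=n_copies, digestion_prob=1.0,
                      adapter_dimer_rate=0.0, seed=seed, **cfg_kw)
    rng = np.random.default_rng(seed)
    frags = f.digest(genome, profile, config=cfg, sites=sites, rng=rng)
    return frags, cfg, rng


def truth_ends(pair):
    """The two AlignedEnd records implied by a simulated pair's ground truth."""
    return (
        f.AlignedEnd(pair.chrom, pair.start, "+", 60, pair.insert_len),
        f.AlignedEnd(pair.chrom, pair.end - 1, "-", 60, pair.insert_len),
    )
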