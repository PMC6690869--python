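import numpy as np
import pytest

from cuckoodedup import ReadRecord, SimSpec, simulate_reads, simulate_reference


def mk(seq: str, rid: str = "r") -> ReadRecord:
    """Shorthand for a record whose quality is all-'I'."""
    return ReadRecord(rid, seq, "", "I" * len(seq))


@pytest.fixture(scope="session")
def sim_suite():
    """102 seeded simulated datasets spanning the validation grid.

    17 rounds x {single, paired} x PCR-duplication lambda in {0, 0.3, 1.0},
    template counts drawn uniformly in [1000, 10000].  Kept in memory and
    shared by the dedup-correctness and cuckoo-fidelity acceptance tests.
    """
    rng = np.random.default_rng(20260929)
    datasets = []
    i = 0
    read_len, cov = 100, 10
    for _ in range(17):
        for lam in (0.0, 0.3, 1.0):
            for paired in (False, True):
                n0 = int(rng.integers(1000, 10001))
                ref_len = n0 * read_len // cov * (2 if paired else 1)
                seed = 1000 + i
                ref = simulate_reference(ref_len, seed=seed)
                spec = SimSpec(
                    read_length=read_len,
                    coverage=cov,
                    paired=paired,
                    duplication_model="poisson" if lam > 0 else "none",
                    duplication_param=lam,
                    seed=seed,
                )
                datasets.append(simulate_reads(ref, spec))
                i += 1
    return datasets
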