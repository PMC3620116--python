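import numpy as np
import pytest

import mscc


@pytest.fixture(scope="session")
def default_dataset() -> mscc.SimulatedDataset:
    """One end-to-end synthetic dataset at default study conditions."""
    return mscc.simulate_dataset(mscc.SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_genome() -> dict[str, str]:
    """Seeded random 10-kb contig for oracle-equivalence checks."""
    rng = np.random.default_rng(1234)
    return {"chrA": "".join(rng.choice(list("ACGT"), size=10_000, p=[0.3, 0.2, 0.2, 0.3]))}


def brute_force_scan(genome: dict[str, str], motifs: dict[str, str]) -> dict[tuple[str, int], set[str]]:
    """Slide every motif and its reverse complement over every offset."""
    from mscc.io import revcomp

    hits: dict[tuple[str, int], set[str]] = {}
    for chrom, seq in genome.items():
        for enzyme, motif in motifs.items():
            for m in {motif, revcomp(motif)}:
                cg = m.find("CG")
                for start in range(len(seq) - len(m) + 1):
                    if seq[start : start + len(m)] == m:
                        hits.setdefault((chrom, start + cg), set()).add(enzyme)
    return hits


DEFAULT_MOTIFS = {"HpaII": "CCGG", "AciI": "CCGC", "HpyCH4IV": "ACGT", "HinP1I": "GCGC"}
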