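import numpy as np
import pytest

import zygocall as z


@pytest.fixture(scope="session")
def mouse():
    return z.mouse_genome()


@pytest.fixture(scope="session")
def one_chrom_genome():
    """A single-chromosome genome for exhaustive outcome enumeration."""
    return z.GenomeModel((z.Chromosome("X", 1_000_000, "X"),))


@pytest.fixture(scope="session")
def toy20():
    """Twenty equal-length chromosomes (19 autosomes + X), no Y."""
    chroms = [z.Chromosome(str(i), 1_000_000, "autosome") for i in range(1, 20)]
    chroms.append(z.Chromosome("X", 1_000_000, "X"))
    return z.GenomeModel(tuple(chroms))


@pytest.fixture(scope="session")
def toy4():
    """Four equal-length chromosomes (3 autosomes + X)."""
    chroms = [z.Chromosome(str(i), 1_000_000, "autosome") for i in (1, 2, 3)]
    chroms.append(z.Chromosome("X", 1_000_000, "X"))
    return z.GenomeModel(tuple(chroms))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def truth_call_set(units: dict[str, int], baseline, sample_id="s") -> z.AneuploidyCallSet:
    """Discrete calls straight from true chromatid units (test-side oracle).

    ``baseline`` is an int applied to every chromosome, or a mapping.
    """
    calls = {}
    for name, u in units.items():
        b = baseline[name] if isinstance(baseline, dict) else baseline
        calls[name] = "gain" if u > b else ("loss" if u < b else "neutral")
    n = sum(c != "neutral" for c in calls.values())
    return z.AneuploidyCallSet(sample_id, calls, n, z.classify_complexity(n))
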