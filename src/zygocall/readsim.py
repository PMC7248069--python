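"""Low-coverage read-count simulation from chromatid-resolution karyotypes.

A whole-genome-amplified single cell sequenced at very low coverage yields,
after alignment, a per-chromosome table of mapped-read counts.  The expected
share of reads on a chromosome is proportional to its DNA mass: chromosome
length times the number of chromatid units present.  Counts are drawn
multinomially at a fixed depth, optionally with Dirichlet overdispersion to
mimic amplification noise.

The overdispersion knob ``rho`` is calibrated to the genome: the Dirichlet
concentration is scaled so that the most weakly represented chromosome has a
relative proportion standard deviation of ``sqrt(rho/(1-rho))`` (about 4.5%
at the default rho=0.002), and every other chromosome less.  ``rho=0`` is
pure multinomial sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meiosim import CellKaryotype, GenomeModel

__all__ = [
    "CountProfile",
    "NoiseModel",
    "expected_proportions",
    "proportions_from_units",
    "euploid_reference_units",
    "simulate_counts",
    "simulate_counts_from_proportions",
    "simulate_reference_cohort",
]

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class CountProfile:
    """Per-chromosome mapped-read counts for one sample."""

    sample_id: str
    sex_label: str  # male | female | unknown
    counts: dict[str, int]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.sex_label not in (FEMALE, MALE, UNKNOWN):
            raise ValueError(f"unknown sex label {self.sex_label!r}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative read count")
        if self.total_mapped != sum(self.counts.values()):
            raise ValueError("total_mapped does not equal the sum of counts")

    @property
    def proportions(self) -> dict[str, float]:
        if self.total_mapped == 0:
            raise ValueError(f"sample {self.sample_id!r} has no mapped reads")
        return {k: v / self.total_mapped for k, v in self.counts.items()}


@dataclass(frozen=True)
class NoiseModel:
    """Sequencing-depth and overdispersion settings.

    ``depth`` is the total mapped reads per sample (the study design point is
    about 200,000).  ``rho`` in [0, 1) sets Dirichlet-multinomial
    overdispersion; 0 means pure multinomial.
    """

    depth: int = 200_000
    rho: float = 0.002

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")


def proportions_from_units(
    units: dict[str, int | float], genome: GenomeModel
) -> dict[str, float]:
    """Expected read proportions for a chromatid-unit map.

    Each chromosome's weight is length_bp x chromatid_units, normalised to
    sum to one over the genome.  Chromosomes absent from ``units`` count as
    zero.  Scale-invariant in the units.
    """
    lengths = genome.lengths
    for name in units:
        if name not in lengths:
            raise KeyError(f"chromosome {name!r} not in genome model")
    weights = np.array(
        [lengths[n] * float(units.get(n, 0)) for n in genome.names], dtype=float
    )
    total = weights.sum()
    if total <= 0:
        raise ValueError("karyotype has no chromatid content")
    return dict(zip(genome.names, weights / total))


def expected_proportions(
    karyotype: CellKaryotype, genome: GenomeModel
) -> dict[str, float]:
    """Expected per-chromosome read proportions of a cell's sequencing library."""
    units = {n: karyotype.chromatid_units(n) for n in karyotype.names}
    return proportions_from_units(units, genome)


def euploid_reference_units(sex: str, genome: GenomeModel) -> dict[str, int]:
    """Chromatid units of a karyotypically normal diploid reference sample."""
    units = {n: 2 for n in genome.autosomes}
    if sex == FEMALE:
        units[genome.x_name] = 2
    elif sex == MALE:
        units[genome.x_name] = 1
        if genome.y_name is None:
            raise ValueError("male reference requires a genome with a Y chromosome")
        units[genome.y_name] = 1
    else:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    return units


def _dirichlet_concentration(p: np.ndarray, rho: float) -> float:
    # Scale so the smallest nonzero proportion has relative SD sqrt(rho/(1-rho)):
    # Var(p_c)/p_c^2 = (1-p_c)/(p_c * alpha0) with alpha0 below.
    p_min = p[p > 0].min()
    return ((1.0 - rho) / rho) * ((1.0 - p_min) / p_min)


def simulate_counts_from_proportions(
    proportions: dict[str, float],
    noise: NoiseModel,
    rng: np.random.Generator,
    sample_id: str = "sample",
    sex_label: str = UNKNOWN,
) -> CountProfile:
    """Draw a count profile at the given expected proportions."""
    names = list(proportions)
    p = np.asarray([proportions[n] for n in names], dtype=float)
    if p.sum() <= 0:
        raise ValueError("proportions must have positive mass")
    p = p / p.sum()
    support = p > 0
    p_eff = p[support]
    if noise.rho > 0:
        alpha0 = _dirichlet_concentration(p_eff, noise.rho)
        p_eff = rng.dirichlet(alpha0 * p_eff)
    counts_eff = rng.multinomial(noise.depth, p_eff)
    counts = np.zeros(len(names), dtype=int)
    counts[support] = counts_eff
    return CountProfile(
        sample_id=sample_id,
        sex_label=sex_label,
        counts={n: int(c) for n, c in zip(names, counts)},
        total_mapped=int(counts.sum()),
    )


def simulate_counts(
    karyotype: CellKaryotype,
    noise: NoiseModel,
    genome: GenomeModel,
    rng: np.random.Generator,
    sample_id: str = "sample",
    sex_label: str = UNKNOWN,
) -> CountProfile:
    """Simulate a low-coverage count profile for one karyotype.

    The total mapped-read count equals ``noise.depth`` exactly; counts on
    chromosomes with zero chromatid content are exactly zero.
    """
    props = expected_proportions(karyotype, genome)
    return simulate_counts_from_proportions(
        props, noise, rng, sample_id=sample_id, sex_label=sex_label
    )


def simulate_reference_cohort(
    n_female: int,
    n_male: int,
    noise: NoiseModel,
    genome: GenomeModel,
    rng: np.random.Generator,
) -> list[CountProfile]:
    """Simulate the euploid reference set used for copy-number normalisation.

    Female references carry no Y content (expected Y proportion is exactly
    zero); male references carry one chromatid unit each of X and Y.
    """
    if n_female < 0 or n_male < 0:
        raise ValueError("cohort sizes must be non-negative")
    if n_female + n_male < 1:
        raise ValueError("reference cohort must contain at least one sample")
    profiles: list[CountProfile] = []
    for sex, n in ((FEMALE, n_female), (MALE, n_male)):
        if n == 0:
            continue
        props = proportions_from_units(euploid_reference_units(sex, genome), genome)
        for i in range(n):
            profiles.append(
                simulate_counts_from_proportions(
                    props,
                    noise,
                    rng,
                    sample_id=f"ref_{sex}_{i + 1:02d}",
                    sex_label=sex,
                )
            )
    return profiles
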