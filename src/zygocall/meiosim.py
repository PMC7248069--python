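"""Chromatid-resolution simulation of female meiosis in crossover-deficient oocytes.

This module models the segregation phenotypes of mouse oocytes in which meiotic
recombination fails: chromosomes that never form a crossover persist as two
unpaired univalents at metaphase I, segregate at random, and may undergo
premature sister-chromatid separation (PSSC), releasing single chromatids that
partition independently.  The simulation tracks every chromosome of every
meiotic product (MII egg, first polar body, zygote, second polar body) at the
resolution of dyads (two sister chromatids under cohesion) and free single
chromatids, so that downstream read-count simulation can weight each
chromosome by its DNA content.

The model:

* **Prophase/metaphase I** — each chromosome pair independently forms a
  crossover-linked bivalent with probability ``p_bivalent``; otherwise it is
  two univalents, each of which independently separates into sisters with
  probability ``p_pssc``.
* **Anaphase I** — a bivalent partitions reductionally (one dyad to the egg,
  one to PB1).  An intact univalent goes whole to either pole with equal
  probability.  A separated univalent's two chromatids segregate
  independently.
* **Anaphase II / fertilisation** — every maternal dyad splits, one chromatid
  to the zygote and one to PB2, except with probability ``p_mii_ndj`` both
  sisters nondisjoin to the same product.  Maternal single chromatids go to
  either product with equal probability.  The sperm then contributes one
  chromatid per autosome plus one sex chromosome (X or Y).

Setting ``p_bivalent=1, p_pssc=0, p_mii_ndj=0`` reproduces a control oocyte
(always euploid); ``p_bivalent=0`` models a fully achiasmate oocyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Chromosome",
    "GenomeModel",
    "mouse_genome",
    "MeiosisParams",
    "CONTROL_PARAMS",
    "MUTANT_PARAMS",
    "PairingState",
    "ProphaseConfig",
    "ChromosomeContent",
    "CellKaryotype",
    "Oocyte",
    "Cohort",
    "MII_EGG",
    "PB1",
    "PB2",
    "ZYGOTE",
    "STAGES",
    "simulate_prophase",
    "segregate_mi",
    "segregate_mii_and_fertilise",
    "simulate_cohort",
    "mii_summary",
    "is_euploid",
]

MII_EGG = "MII_egg"
PB1 = "PB1"
PB2 = "PB2"
ZYGOTE = "zygote"
STAGES = (MII_EGG, PB1, PB2, ZYGOTE)

AUTOSOME = "autosome"
X = "X"
Y = "Y"

# GRCm38 chromosome lengths (bp), the coordinate frame of the count tables.
_MOUSE_LENGTHS = {
    "1": 195_471_971,
    "2": 182_113_224,
    "3": 160_039_680,
    "4": 156_508_116,
    "5": 151_834_684,
    "6": 149_736_546,
    "7": 145_441_459,
    "8": 129_401_213,
    "9": 124_595_110,
    "10": 130_694_993,
    "11": 122_082_543,
    "12": 120_129_022,
    "13": 120_421_639,
    "14": 124_902_244,
    "15": 104_043_685,
    "16": 98_207_768,
    "17": 94_987_271,
    "18": 90_702_639,
    "19": 61_431_566,
    "X": 171_031_299,
    "Y": 91_744_698,
}


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the genome model."""

    name: str
    length_bp: int
    cls: str  # autosome | X | Y

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be positive")
        if self.cls not in (AUTOSOME, X, Y):
            raise ValueError(f"chromosome {self.name!r}: unknown class {self.cls!r}")


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome set with lengths and sex class.

    Exactly one X is required; the Y is optional (absent from oocyte-only
    genomes).  The default mouse model (:func:`mouse_genome`) has 19 autosomes
    plus X and Y.
    """

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names in genome model")
        n_x = sum(c.cls == X for c in self.chromosomes)
        n_y = sum(c.cls == Y for c in self.chromosomes)
        if n_x != 1:
            raise ValueError(f"genome must contain exactly one X (got {n_x})")
        if n_y > 1:
            raise ValueError(f"genome may contain at most one Y (got {n_y})")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length_bp for c in self.chromosomes}

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes if c.cls == AUTOSOME)

    @property
    def x_name(self) -> str:
        return next(c.name for c in self.chromosomes if c.cls == X)

    @property
    def y_name(self) -> str | None:
        return next((c.name for c in self.chromosomes if c.cls == Y), None)

    @property
    def female_names(self) -> tuple[str, ...]:
        """Chromosomes present in the oocyte: all autosomes plus X, never Y."""
        return tuple(c.name for c in self.chromosomes if c.cls != Y)

    def cls_of(self, name: str) -> str:
        for c in self.chromosomes:
            if c.name == name:
                return c.cls
        raise KeyError(name)


def mouse_genome() -> GenomeModel:
    """The default GRCm38 mouse genome model: 19 autosomes + X + Y."""
    chroms = [
        Chromosome(n, l, AUTOSOME if n.isdigit() else n)
        for n, l in _MOUSE_LENGTHS.items()
    ]
    return GenomeModel(tuple(chroms))


@dataclass(frozen=True)
class MeiosisParams:
    """Segregation-error probabilities for one simulated oocyte cohort.

    Parameters
    ----------
    p_bivalent:
        Probability that a homolog pair is held together by a crossover.
        1 models recombination-proficient controls; 0 models an oocyte in
        which every chromosome is an unpaired univalent.
    p_pssc:
        Probability that an individual univalent undergoes premature sister
        separation before anaphase I.
    p_mii_ndj:
        Probability that a dyad nondisjoins at anaphase II (both sisters to
        the same product).
    seed:
        Optional RNG seed recorded with simulated cohorts.
    """

    p_bivalent: float
    p_pssc: float = 0.0
    p_mii_ndj: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for nm in ("p_bivalent", "p_pssc", "p_mii_ndj"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1], got {v}")


#: Recombination-proficient control oocyte: every chromosome a bivalent.
CONTROL_PARAMS = MeiosisParams(p_bivalent=1.0, p_pssc=0.0, p_mii_ndj=0.0)
#: Achiasmate oocyte: all univalents, half of them separating prematurely.
MUTANT_PARAMS = MeiosisParams(p_bivalent=0.0, p_pssc=0.5, p_mii_ndj=0.0)

BIVALENT = "bivalent"
UNIVALENTS = "univalents"


@dataclass(frozen=True)
class PairingState:
    """Metaphase-I configuration of one homolog pair.

    ``kind`` is ``"bivalent"`` or ``"univalents"``; for univalents,
    ``separated`` flags whether each of the two univalents has undergone
    premature sister separation.
    """

    kind: str
    separated: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        if self.kind not in (BIVALENT, UNIVALENTS):
            raise ValueError(f"unknown pairing state {self.kind!r}")


@dataclass(frozen=True)
class ProphaseConfig:
    """Per-chromosome metaphase-I configuration of one oocyte."""

    states: dict[str, PairingState]


@dataclass(frozen=True)
class ChromosomeContent:
    """Dyad/single-chromatid content of one chromosome in one cell."""

    dyads: int = 0
    singles: int = 0

    def __post_init__(self) -> None:
        if self.dyads < 0 or self.singles < 0:
            raise ValueError("dyads and singles must be non-negative")

    @property
    def chromatid_units(self) -> int:
        return 2 * self.dyads + self.singles


_EMPTY = ChromosomeContent()


@dataclass(frozen=True)
class CellKaryotype:
    """Chromatid-resolution karyotype of one meiotic product.

    ``content`` holds the maternal complement.  For zygotes the paternal
    contribution (one chromatid per autosome plus one sex chromosome) is
    recorded separately in ``paternal``.
    """

    stage: str
    content: dict[str, ChromosomeContent]
    paternal: dict[str, ChromosomeContent] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.paternal is not None and self.stage != ZYGOTE:
            raise ValueError("only zygotes carry a paternal complement")

    def chromatid_units(self, name: str) -> int:
        """Total chromatid units (maternal + paternal) for one chromosome."""
        units = self.content.get(name, _EMPTY).chromatid_units
        if self.paternal is not None:
            units += self.paternal.get(name, _EMPTY).chromatid_units
        return units

    @property
    def names(self) -> tuple[str, ...]:
        names = dict.fromkeys(self.content)
        if self.paternal is not None:
            names.update(dict.fromkeys(self.paternal))
        return tuple(names)


def simulate_prophase(
    params: MeiosisParams, genome: GenomeModel, rng: np.random.Generator
) -> ProphaseConfig:
    """Draw the metaphase-I configuration of one oocyte.

    Each chromosome of the female complement (autosomes + X) is independently
    a bivalent with probability ``p_bivalent``; otherwise its two univalents
    each separate prematurely with probability ``p_pssc``.
    """
    states: dict[str, PairingState] = {}
    for name in genome.female_names:
        if rng.random() < params.p_bivalent:
            states[name] = PairingState(BIVALENT)
        else:
            sep = (rng.random() < params.p_pssc, rng.random() < params.p_pssc)
            states[name] = PairingState(UNIVALENTS, sep)
    return ProphaseConfig(states)


def segregate_mi(
    config: ProphaseConfig, rng: np.random.Generator
) -> tuple[CellKaryotype, CellKaryotype]:
    """Anaphase I: partition each chromosome between the MII egg and PB1.

    Bivalents divide reductionally (one dyad each way).  Intact univalents go
    whole to a random pole; separated univalents release two chromatids that
    segregate independently.  Chromatid conservation (4 units per chromosome
    across egg + PB1) holds by construction.
    """
    egg: dict[str, ChromosomeContent] = {}
    pb1: dict[str, ChromosomeContent] = {}
    for name, state in config.states.items():
        e_dy = e_sg = p_dy = p_sg = 0
        if state.kind == BIVALENT:
            e_dy, p_dy = 1, 1
        else:
            for sep in state.separated:
                if not sep:
                    if rng.random() < 0.5:
                        e_dy += 1
                    else:
                        p_dy += 1
                else:
                    for _ in range(2):
                        if rng.random() < 0.5:
                            e_sg += 1
                        else:
                            p_sg += 1
        egg[name] = ChromosomeContent(e_dy, e_sg)
        pb1[name] = ChromosomeContent(p_dy, p_sg)
    return CellKaryotype(MII_EGG, egg), CellKaryotype(PB1, pb1)


def segregate_mii_and_fertilise(
    egg: CellKaryotype,
    params: MeiosisParams,
    paternal_sex_chromosome: str,
    genome: GenomeModel,
    rng: np.random.Generator,
) -> tuple[CellKaryotype, CellKaryotype]:
    """Anaphase II plus fertilisation: egg -> (zygote, PB2).

    Each maternal dyad normally sends one sister chromatid to the zygote and
    one to PB2; with probability ``p_mii_ndj`` both sisters nondisjoin to the
    same product (either one with equal probability).  Maternal single
    chromatids partition at random.  The zygote then gains one paternal
    chromatid per autosome plus one chromatid of the stated sex chromosome.
    All post-MII content is single chromatids.
    """
    if egg.stage != MII_EGG:
        raise ValueError(f"expected an MII egg, got stage {egg.stage!r}")
    if paternal_sex_chromosome not in (X, Y):
        raise ValueError("paternal sex chromosome must be 'X' or 'Y'")
    zyg: dict[str, ChromosomeContent] = {}
    pb2: dict[str, ChromosomeContent] = {}
    for name, cc in egg.content.items():
        z = p = 0
        for _ in range(cc.dyads):
            if rng.random() < params.p_mii_ndj:
                if rng.random() < 0.5:
                    z += 2
                else:
                    p += 2
            else:
                z += 1
                p += 1
        for _ in range(cc.singles):
            if rng.random() < 0.5:
                z += 1
            else:
                p += 1
        zyg[name] = ChromosomeContent(singles=z)
        pb2[name] = ChromosomeContent(singles=p)
    paternal = {name: ChromosomeContent(singles=1) for name in genome.autosomes}
    sex_name = genome.x_name if paternal_sex_chromosome == X else genome.y_name
    if sex_name is None:
        raise ValueError("genome has no Y chromosome for a male paternal gamete")
    paternal[sex_name] = ChromosomeContent(singles=1)
    zygote = CellKaryotype(ZYGOTE, zyg, paternal=paternal)
    return zygote, CellKaryotype(PB2, pb2)


@dataclass(frozen=True)
class Oocyte:
    """All four products of one simulated oocyte."""

    index: int
    paternal_sex: str  # "X" or "Y"
    egg: CellKaryotype
    pb1: CellKaryotype
    zygote: CellKaryotype
    pb2: CellKaryotype


@dataclass(frozen=True)
class Cohort:
    """A set of independently simulated oocytes plus the generating settings."""

    oocytes: tuple[Oocyte, ...]
    params: MeiosisParams
    seed: int | None

    def __len__(self) -> int:
        return len(self.oocytes)

    def __iter__(self):
        return iter(self.oocytes)


def simulate_cohort(
    n: int,
    params: MeiosisParams,
    genome: GenomeModel | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Simulate ``n`` independent oocytes through MI, MII and fertilisation.

    The paternal sex chromosome is X or Y with equal probability.  When no
    generator is supplied, one is created from ``params.seed``, making the
    cohort bit-reproducible.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    genome = genome or mouse_genome()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out = []
    for i in range(n):
        config = simulate_prophase(params, genome, rng)
        egg, pb1 = segregate_mi(config, rng)
        pat = X if (genome.y_name is None or rng.random() < 0.5) else Y
        zygote, pb2 = segregate_mii_and_fertilise(egg, params, pat, genome, rng)
        out.append(Oocyte(i, pat, egg, pb1, zygote, pb2))
    return Cohort(tuple(out), replace(params), params.seed)


def mii_summary(egg: CellKaryotype) -> tuple[int, int]:
    """Count (chromosomes, single chromatids) in a metaphase-II egg.

    "Chromosomes" here are dyads, the cytological counting unit at MII; a
    euploid mouse egg scores (20, 0).
    """
    if egg.stage != MII_EGG:
        raise ValueError(f"mii_summary requires an MII egg, got {egg.stage!r}")
    n_chrom = sum(cc.dyads for cc in egg.content.values())
    n_chromatid = sum(cc.singles for cc in egg.content.values())
    return n_chrom, n_chromatid


def is_euploid(karyotype: CellKaryotype, genome: GenomeModel) -> bool:
    """True when the cell carries exactly the normal complement for its stage.

    MII egg / PB1: one dyad, no singles, per female chromosome.  PB2: one
    single chromatid per female chromosome.  Zygote: one maternal chromatid
    per female chromosome plus the full paternal set.
    """
    if karyotype.stage in (MII_EGG, PB1):
        return all(
            karyotype.content.get(n, _EMPTY) == ChromosomeContent(dyads=1)
            for n in genome.female_names
        )
    if karyotype.stage == PB2:
        return all(
            karyotype.content.get(n, _EMPTY) == ChromosomeContent(singles=1)
            for n in genome.female_names
        )
    # Zygote: maternal complement must be exactly one chromatid per female
    # chromosome; the paternal complement is one chromatid per autosome plus
    # one sex chromosome by construction.
    maternal_ok = all(
        karyotype.content.get(n, _EMPTY) == ChromosomeContent(singles=1)
        for n in genome.female_names
    )
    if karyotype.paternal is None:
        return False
    pat_auto = all(
        karyotype.paternal.get(n, _EMPTY).chromatid_units == 1
        for n in genome.autosomes
    )
    sex_units = sum(
        karyotype.paternal.get(n, _EMPTY).chromatid_units
        for n in (genome.x_name, genome.y_name)
        if n is not None
    )
    return maternal_ok and pat_auto and sex_units == 1
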