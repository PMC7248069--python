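"""Read-proportion copy-number inference and whole-chromosome aneuploidy calls.

The procedure works entirely on relative read shares.  For a test sample, the
proportion of mapped reads on each chromosome is divided by the mean
proportion in a reference set of karyotypically normal samples, giving a
ratio that is 1 for a chromosome present at reference dosage.  Ratios are
then placed on the diploid-autosome scale: doubled for all chromosomes in
female samples and for autosomes in male samples, while male X and Y ratios
are kept as-is because those chromosomes are single-copy in a euploid male.
A euploid chromosome therefore reads CN = 2 (or 1 for male X/Y).

Calls are thresholded on the relative deviation from that baseline; samples
are classified euploid (no aneuploid chromosome), simple (one or two) or
complex (three or more aneuploid chromosomes).

Polar bodies are haploid-scale samples, but because only proportions enter
the ratio they are analysed identically, against the female reference (a
polar body has one chromatid per autosome and per X, i.e. the female
*pattern* of relative proportions), and their calls are read against the
same relative baseline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .meiosim import GenomeModel
from .readsim import FEMALE, MALE, CountProfile

__all__ = [
    "ReferenceProfile",
    "CopyNumberProfile",
    "CallThresholds",
    "AneuploidyCallSet",
    "SEX_MATCHED",
    "POOLED",
    "EUPLOID",
    "SIMPLE",
    "COMPLEX",
    "GAIN",
    "LOSS",
    "NEUTRAL",
    "build_reference",
    "infer_sex",
    "predict_copy_number",
    "predict_copy_number_from_proportions",
    "call_aneuploidy",
    "classify_complexity",
]

SEX_MATCHED = "sex_matched"
POOLED = "pooled"

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

EUPLOID = "euploid"
SIMPLE = "simple"
COMPLEX = "complex"


@dataclass(frozen=True)
class ReferenceProfile:
    """Mean reference read proportions, per sex or pooled.

    In ``sex_matched`` mode ``proportions`` maps ``"female"`` and ``"male"``
    to per-chromosome mean proportions; in ``pooled`` mode it holds a single
    ``"pooled"`` entry averaged over all reference samples regardless of sex.
    """

    proportions: dict[str, dict[str, float]]
    n_female: int
    n_male: int
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in (SEX_MATCHED, POOLED):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        for sex, props in self.proportions.items():
            s = sum(props.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{sex} reference proportions sum to {s}, not 1")

    def for_sex(self, sex: str) -> dict[str, float]:
        """Reference proportions to normalise a sample of the given sex."""
        key = POOLED if self.mode == POOLED else sex
        try:
            return self.proportions[key]
        except KeyError:
            raise ValueError(f"reference has no {key!r} proportions") from None


@dataclass(frozen=True)
class CopyNumberProfile:
    """Continuous predicted copy number per chromosome, diploid-autosome scale."""

    sample_id: str
    sex_used: str
    ratios: dict[str, float]
    copy_number: dict[str, float]
    absent: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = list(self.copy_number.values())
        if any(not np.isfinite(v) or v < 0 for v in vals):
            raise ValueError("copy numbers must be finite and non-negative")


@dataclass(frozen=True)
class CallThresholds:
    """Relative deviation from baseline required to call a gain or loss."""

    delta_rel: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_rel < 1.0:
            raise ValueError(f"delta_rel must be in (0, 1), got {self.delta_rel}")


@dataclass(frozen=True)
class AneuploidyCallSet:
    """Discrete gain/loss calls with a whole-sample complexity class."""

    sample_id: str
    calls: dict[str, str]
    n_aneuploid: int
    complexity: str

    def __post_init__(self) -> None:
        if any(c not in (GAIN, LOSS, NEUTRAL) for c in self.calls.values()):
            raise ValueError("calls must be gain, loss or neutral")
        n = sum(c != NEUTRAL for c in self.calls.values())
        if n != self.n_aneuploid:
            raise ValueError("n_aneuploid inconsistent with the call map")
        if self.complexity != classify_complexity(self):
            raise ValueError("complexity inconsistent with n_aneuploid")


def build_reference(
    profiles: list[CountProfile], mode: str = SEX_MATCHED
) -> ReferenceProfile:
    """Average reference-sample read proportions into a normalisation profile.

    ``sex_matched`` keeps separate female and male means (and requires at
    least one sample of each sex); ``pooled`` averages every sample into a
    single profile regardless of sex.
    """
    if not profiles:
        raise ValueError("reference set is empty")
    names = list(profiles[0].counts)
    for p in profiles:
        if list(p.counts) != names:
            raise ValueError(
                f"reference sample {p.sample_id!r} covers a different chromosome set"
            )
    by_sex = Counter(p.sex_label for p in profiles)
    if mode == SEX_MATCHED:
        if by_sex.get(FEMALE, 0) == 0 or by_sex.get(MALE, 0) == 0:
            raise ValueError(
                "sex_matched reference requires at least one female and one male "
                f"sample (got {by_sex.get(FEMALE, 0)} female, {by_sex.get(MALE, 0)} male)"
            )
        props = {}
        for sex in (FEMALE, MALE):
            mats = np.array(
                [[p.proportions[n] for n in names] for p in profiles if p.sex_label == sex]
            )
            props[sex] = dict(zip(names, mats.mean(axis=0)))
    elif mode == POOLED:
        mats = np.array([[p.proportions[n] for n in names] for p in profiles])
        props = {POOLED: dict(zip(names, mats.mean(axis=0)))}
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    return ReferenceProfile(
        proportions=props,
        n_female=by_sex.get(FEMALE, 0),
        n_male=by_sex.get(MALE, 0),
        mode=mode,
    )


def infer_sex(profile: CountProfile, ref: ReferenceProfile, genome: GenomeModel) -> str:
    """Sex a sample from its Y-chromosome read share.

    A sample is called male when its Y proportion is at least half the male
    reference's Y proportion, which cleanly separates one Y copy from none at
    the depths involved.
    """
    if ref.mode != SEX_MATCHED:
        raise ValueError("sex inference requires a sex_matched reference")
    y = genome.y_name
    if y is None:
        return FEMALE
    ref_y = ref.proportions[MALE].get(y, 0.0)
    if ref_y <= 0:
        raise ValueError("male reference has zero Y proportion; cannot infer sex")
    return MALE if profile.proportions.get(y, 0.0) >= 0.5 * ref_y else FEMALE


def predict_copy_number_from_proportions(
    proportions: dict[str, float],
    ref: ReferenceProfile,
    sex: str,
    genome: GenomeModel,
    sample_id: str = "sample",
) -> CopyNumberProfile:
    """Copy-number profile from exact read proportions (noise-free entry point).

    The ratio to the (sex-matched, or pooled) reference proportion is doubled
    for autosomes and for the female X; male X and Y keep the raw ratio.
    Chromosomes with zero reference proportion for this sex (the female Y)
    are reported as absent, provided the sample also has no reads there.
    """
    if sex not in (FEMALE, MALE):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    ref_props = ref.for_sex(sex)
    ratios: dict[str, float] = {}
    cn: dict[str, float] = {}
    absent: list[str] = []
    for name, p in proportions.items():
        rp = ref_props.get(name, 0.0)
        if rp <= 0.0:
            if p > 0.0:
                raise ValueError(
                    f"chromosome {name!r} has reads but zero reference proportion "
                    f"for sex {sex!r}: inconsistent reference"
                )
            absent.append(name)
            continue
        r = p / rp
        ratios[name] = r
        single_copy = sex == MALE and genome.cls_of(name) in ("X", "Y")
        cn[name] = r if single_copy else 2.0 * r
    return CopyNumberProfile(
        sample_id=sample_id,
        sex_used=sex,
        ratios=ratios,
        copy_number=cn,
        absent=tuple(absent),
    )


def predict_copy_number(
    profile: CountProfile,
    ref: ReferenceProfile,
    sex: str,
    genome: GenomeModel,
) -> CopyNumberProfile:
    """Copy-number profile for a count profile (see module docstring)."""
    return predict_copy_number_from_proportions(
        profile.proportions, ref, sex, genome, sample_id=profile.sample_id
    )


def baseline_copy_number(name: str, sex: str, genome: GenomeModel) -> float:
    """Euploid copy number on the reported scale: 1 for male X/Y, else 2."""
    if sex == MALE and genome.cls_of(name) in ("X", "Y"):
        return 1.0
    return 2.0


def call_aneuploidy(
    cnp: CopyNumberProfile,
    thresholds: CallThresholds,
    genome: GenomeModel,
) -> AneuploidyCallSet:
    """Threshold copy numbers into gain/loss/neutral calls per chromosome.

    A chromosome is a gain when CN/baseline - 1 >= delta_rel and a loss when
    1 - CN/baseline >= delta_rel.  The sample is then classed euploid /
    simple / complex from the number of aneuploid chromosomes.
    """
    calls: dict[str, str] = {}
    for name, cn in cnp.copy_number.items():
        b = baseline_copy_number(name, cnp.sex_used, genome)
        dev = cn / b - 1.0
        if dev >= thresholds.delta_rel:
            calls[name] = GAIN
        elif -dev >= thresholds.delta_rel:
            calls[name] = LOSS
        else:
            calls[name] = NEUTRAL
    n = sum(c != NEUTRAL for c in calls.values())
    return AneuploidyCallSet(
        sample_id=cnp.sample_id,
        calls=calls,
        n_aneuploid=n,
        complexity=_complexity_from_count(n),
    )


def _complexity_from_count(n_aneuploid: int) -> str:
    if n_aneuploid == 0:
        return EUPLOID
    if n_aneuploid <= 2:
        return SIMPLE
    return COMPLEX


def classify_complexity(calls: "AneuploidyCallSet | int") -> str:
    """Complexity class: euploid (0), simple (1-2) or complex (>=3 chromosomes)."""
    if isinstance(calls, int):
        return _complexity_from_count(calls)
    return _complexity_from_count(sum(c != NEUTRAL for c in calls.calls.values()))
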