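"""Matched zygote / polar-body reciprocity analysis and cohort summaries.

Because the second polar body receives exactly the chromatids the egg did not
keep at anaphase II, a mis-partition that leaves the zygote with extra
material of a chromosome should leave the matched polar body depleted for it,
and vice versa.  This module compares discrete aneuploidy calls between a
zygote and its polar body chromosome by chromosome, labels each chromosome
reciprocal / concordant / unmatched / neutral, and summarises a cohort as a
heatmap-ready matrix of copy-number deviations plus headline fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnvcall import (
    COMPLEX,
    GAIN,
    LOSS,
    NEUTRAL,
    AneuploidyCallSet,
    CopyNumberProfile,
    baseline_copy_number,
)
from .meiosim import GenomeModel

__all__ = [
    "RECIPROCAL",
    "CONCORDANT",
    "UNMATCHED",
    "PairReciprocityReport",
    "CohortMatrix",
    "reciprocity",
    "cohort_summary",
]

RECIPROCAL = "reciprocal"
CONCORDANT = "concordant"
UNMATCHED = "unmatched"


@dataclass(frozen=True)
class PairReciprocityReport:
    """Per-chromosome call comparison for one zygote/polar-body pair.

    ``reciprocity_fraction`` is computed over chromosomes aneuploid in the
    polar body: the fraction whose zygote call has the opposite sign.  When
    the polar body has no aneuploid chromosome the fraction is undefined
    (``None``) and flagged.
    """

    pair_id: str
    relations: dict[str, tuple[str, str, str]]  # chrom -> (zygote, pb, relation)
    n_reciprocal: int
    n_concordant: int
    n_unmatched: int
    n_neutral: int
    reciprocity_fraction: float | None

    @property
    def undefined(self) -> bool:
        return self.reciprocity_fraction is None


@dataclass(frozen=True)
class CohortMatrix:
    """Samples-by-chromosomes matrices of CN deviation and discrete calls."""

    deviations: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.deviations.index.is_unique or not self.deviations.columns.is_unique:
            raise ValueError("cohort matrix labels must be unique")
        if not self.deviations.index.equals(self.calls.index) or not (
            self.deviations.columns.equals(self.calls.columns)
        ):
            raise ValueError("deviation and call matrices must be aligned")


def _relation(z_call: str, pb_call: str) -> str:
    if z_call == NEUTRAL and pb_call == NEUTRAL:
        return NEUTRAL
    if NEUTRAL in (z_call, pb_call):
        return UNMATCHED
    return RECIPROCAL if z_call != pb_call else CONCORDANT


def reciprocity(
    zygote: AneuploidyCallSet,
    pb: AneuploidyCallSet,
    genome: GenomeModel,
    pair_id: str | None = None,
) -> PairReciprocityReport:
    """Compare a zygote's calls with its matched polar body's calls.

    The comparison runs over the chromosomes shared by both call sets,
    excluding the Y (a polar body carries no Y).  Both call sets must cover
    the same non-Y chromosomes.
    """
    y = genome.y_name
    z_names = {n for n in zygote.calls if n != y}
    p_names = {n for n in pb.calls if n != y}
    if z_names != p_names:
        raise ValueError(
            f"pair {pair_id or zygote.sample_id!r}: zygote and polar body cover "
            "different chromosome sets"
        )
    relations: dict[str, tuple[str, str, str]] = {}
    counts = {RECIPROCAL: 0, CONCORDANT: 0, UNMATCHED: 0, NEUTRAL: 0}
    n_pb_aneuploid = 0
    n_pb_reciprocal = 0
    for name in (n for n in zygote.calls if n in z_names):
        zc, pc = zygote.calls[name], pb.calls[name]
        rel = _relation(zc, pc)
        relations[name] = (zc, pc, rel)
        counts[rel] += 1
        if pc != NEUTRAL:
            n_pb_aneuploid += 1
            if rel == RECIPROCAL:
                n_pb_reciprocal += 1
    frac = n_pb_reciprocal / n_pb_aneuploid if n_pb_aneuploid else None
    return PairReciprocityReport(
        pair_id=pair_id or f"{zygote.sample_id}|{pb.sample_id}",
        relations=relations,
        n_reciprocal=counts[RECIPROCAL],
        n_concordant=counts[CONCORDANT],
        n_unmatched=counts[UNMATCHED],
        n_neutral=counts[NEUTRAL],
        reciprocity_fraction=frac,
    )


def cohort_summary(
    pairs: list[PairReciprocityReport],
    zygote_calls: list[AneuploidyCallSet],
    pb_calls: list[AneuploidyCallSet],
    genome: GenomeModel,
    zygote_cn: list[CopyNumberProfile] | None = None,
    pb_cn: list[CopyNumberProfile] | None = None,
) -> tuple[CohortMatrix, dict]:
    """Cohort-level matrix and headline numbers for a set of matched pairs.

    The summary reports, without deciding any hypothesis test: the fraction
    of zygotes classified complex-aneuploid, the mean of the defined
    per-pair reciprocity fractions, per-chromosome aneuploidy frequencies
    over all samples, and a chi-square uniformity statistic of aneuploidy
    events across autosomes (a diagnostic for chromosome preference).
    """
    if not pairs:
        raise ValueError("cohort is empty")
    if len(zygote_calls) != len(pairs) or len(pb_calls) != len(pairs):
        raise ValueError("one zygote and one polar-body call set required per pair")

    # Heatmap matrix: CN deviation from the euploid baseline when profiles are
    # supplied, else signed unit deviations from the discrete calls.
    chroms = [n for n in genome.names]
    rows: dict[str, dict[str, float]] = {}
    call_rows: dict[str, dict[str, str]] = {}

    def add_row(label: str, calls: AneuploidyCallSet, cnp: CopyNumberProfile | None):
        if cnp is not None:
            dev = {
                n: cnp.copy_number[n] - baseline_copy_number(n, cnp.sex_used, genome)
                for n in cnp.copy_number
            }
        else:
            dev = {n: {GAIN: 1.0, LOSS: -1.0, NEUTRAL: 0.0}[c] for n, c in calls.calls.items()}
        rows[label] = {n: dev.get(n, np.nan) for n in chroms}
        call_rows[label] = {n: calls.calls.get(n, "") for n in chroms}

    for i, pair in enumerate(pairs):
        zc, pc = zygote_calls[i], pb_calls[i]
        add_row(f"{pair.pair_id}:zygote", zc, zygote_cn[i] if zygote_cn else None)
        add_row(f"{pair.pair_id}:pb", pc, pb_cn[i] if pb_cn else None)

    deviations = pd.DataFrame.from_dict(rows, orient="index")[chroms]
    calls_df = pd.DataFrame.from_dict(call_rows, orient="index")[chroms]
    matrix = CohortMatrix(deviations=deviations, calls=calls_df)

    all_calls = list(zygote_calls) + list(pb_calls)
    per_chrom_freq = {
        n: float(
            np.mean([cs.calls.get(n, NEUTRAL) != NEUTRAL for cs in all_calls])
        )
        for n in chroms
    }
    auto_counts = np.array(
        [
            sum(cs.calls.get(n, NEUTRAL) != NEUTRAL for cs in all_calls)
            for n in genome.autosomes
        ],
        dtype=float,
    )
    if auto_counts.sum() > 0:
        chi2, pval = stats.chisquare(auto_counts)
        uniformity = {
            "chi2": float(chi2),
            "dof": int(len(auto_counts) - 1),
            "p_value": float(pval),
        }
    else:
        uniformity = {"chi2": 0.0, "dof": int(len(auto_counts) - 1), "p_value": 1.0}

    defined = [p.reciprocity_fraction for p in pairs if p.reciprocity_fraction is not None]
    summary = {
        "n_pairs": len(pairs),
        "fraction_zygotes_complex": float(
            np.mean([cs.complexity == COMPLEX for cs in zygote_calls])
        ),
        "fraction_zygotes_euploid": float(
            np.mean([cs.n_aneuploid == 0 for cs in zygote_calls])
        ),
        "mean_reciprocity_fraction": float(np.mean(defined)) if defined else None,
        "n_pairs_reciprocity_defined": len(defined),
        "per_chromosome_aneuploidy_frequency": per_chrom_freq,
        "autosome_uniformity": uniformity,
    }
    return matrix, summary
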