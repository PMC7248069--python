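"""File formats and run configuration for the aneuploidy pipeline.

Count tables use the samtools-idxstats TSV dialect (chrom, length, mapped,
unmapped), one file per sample, tied together by a manifest TSV.  Karyotypes
are serialised as JSON lines; references, copy-number calls and pair reports
as TSVs.  Every file written here starts with ``#`` comment lines recording
the tool version, the seed and a hash of the run configuration, and every
reader skips such lines, so outputs round-trip exactly.

Chromosome names are normalised to the canonical bare forms ("1".."19",
"X", "Y"): a leading "chr" prefix is stripped and "M"/"chrM" maps to "MT".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cnvcall import AneuploidyCallSet, CopyNumberProfile, ReferenceProfile
from .meiosim import CellKaryotype, ChromosomeContent, Chromosome, GenomeModel
from .readsim import FEMALE, MALE, UNKNOWN, CountProfile

__all__ = [
    "ParseError",
    "RunConfig",
    "normalise_chrom",
    "read_idxstats",
    "write_idxstats",
    "read_manifest",
    "write_manifest",
    "write_karyotypes_jsonl",
    "read_karyotypes_jsonl",
    "write_reference",
    "read_reference",
    "write_calls_table",
    "read_calls_table",
    "read_genome_table",
    "header_lines",
]

log = logging.getLogger("zygocall")

_ALIASES = {"M": "MT", "CHRM": "MT"}


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""


def normalise_chrom(name: str) -> str:
    """Map an input chromosome label onto the canonical bare name."""
    n = name.strip()
    if n.lower().startswith("chr"):
        n = n[3:]
    return _ALIASES.get(n.upper(), n)


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run; serialisable to YAML."""

    genome: str = "mouse"  # "mouse" or path to a chromosome-lengths TSV
    n: int = 10
    p_bivalent: float = 0.0
    p_pssc: float = 0.5
    p_mii_ndj: float = 0.0
    depth: int = 200_000
    rho: float = 0.002
    delta_rel: float = 0.2
    ref_mode: str = "sex_matched"
    n_ref_female: int = 10
    n_ref_male: int = 10
    seed: int = 0
    out: str = "zygocall_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        # Hash the scientific settings only, not the output location, so the
        # same run written to two directories is recognisably identical.
        data = {k: v for k, v in asdict(self).items() if k != "out"}
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(seed: int | None = None, config: RunConfig | None = None) -> list[str]:
    """Standard comment header for every output file (no timestamps: outputs
    must be byte-identical across reruns of the same seed)."""
    lines = [f"# zygocall v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config.config_hash}")
    return lines


def _write_with_header(path: Path, body: str, seed=None, config=None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(header_lines(seed, config)) + "\n" + body)


# ---------------------------------------------------------------------------
# Genome tables


def read_genome_table(path: str | Path) -> GenomeModel:
    """Load a genome model from a TSV of (name, length_bp[, class]) rows.

    Without a class column, numeric names are autosomes and "X"/"Y" are the
    sex chromosomes.
    """
    chroms = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
        name = normalise_chrom(parts[0])
        try:
            length = int(parts[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from None
        cls = parts[2] if len(parts) > 2 and parts[2] else (
            name if name in ("X", "Y") else "autosome"
        )
        chroms.append(Chromosome(name, length, cls))
    if not chroms:
        raise ParseError(f"{path}: no chromosomes")
    return GenomeModel(tuple(chroms))


# ---------------------------------------------------------------------------
# idxstats count tables


def read_idxstats(
    path: str | Path,
    genome: GenomeModel | None = None,
    sample_id: str | None = None,
    sex_label: str = UNKNOWN,
    strict: bool = True,
) -> CountProfile:
    """Parse a samtools-idxstats-style TSV into a count profile.

    Expects >=3 tab-separated columns (chrom, length, mapped[, unmapped]);
    ``*``-named unplaced bins and ``#`` comments are skipped.  With a genome
    model, chromosome names are normalised, lengths are cross-checked within
    1%, and chromosomes outside the model are an error (``strict=True``) or
    dropped with a warning (``strict=False``); model chromosomes missing from
    the file get count zero.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
        name = parts[0].strip()
        if name == "*":
            continue
        name = normalise_chrom(name)
        try:
            length = int(parts[1])
            mapped = int(parts[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer length/mapped field") from None
        if mapped < 0:
            raise ParseError(f"{path}:{lineno}: negative mapped count {mapped}")
        if name in counts:
            raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        if genome is not None:
            if name not in genome.names:
                if strict:
                    raise ParseError(
                        f"{path}:{lineno}: chromosome {name!r} not in genome model"
                    )
                log.warning("%s:%d: dropping unknown chromosome %r", path, lineno, name)
                continue
            expected = genome.lengths[name]
            if abs(length - expected) > 0.01 * expected:
                raise ParseError(
                    f"{path}:{lineno}: length {length} for {name!r} differs from "
                    f"genome model ({expected}) by more than 1%"
                )
        counts[name] = mapped
    if genome is not None:
        counts = {n: counts.get(n, 0) for n in genome.names}
    if not counts:
        raise ParseError(f"{path}: no usable rows")
    return CountProfile(
        sample_id=sample_id or path.stem,
        sex_label=sex_label,
        counts=counts,
        total_mapped=sum(counts.values()),
    )


def write_idxstats(
    profile: CountProfile,
    genome: GenomeModel,
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write a count profile in the idxstats dialect (unmapped column = 0)."""
    lengths = genome.lengths
    body = "".join(
        f"{n}\t{lengths[n]}\t{profile.counts.get(n, 0)}\t0\n" for n in genome.names
    )
    _write_with_header(Path(path), body, seed, config)


# ---------------------------------------------------------------------------
# Manifests

_MANIFEST_COLS = ["sample_id", "sex_label", "role", "stage", "pair_id", "path"]


def write_manifest(
    rows: list[dict],
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write the cohort manifest TSV (one row per sample)."""
    df = pd.DataFrame(rows, columns=_MANIFEST_COLS).fillna("")
    body = df.to_csv(sep="\t", index=False)
    _write_with_header(Path(path), body, seed, config)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in ("sample_id", "sex_label", "role", "path") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    return df


# ---------------------------------------------------------------------------
# Karyotype JSON


def _content_to_json(content: dict[str, ChromosomeContent]) -> dict:
    return {n: {"dyads": c.dyads, "singles": c.singles} for n, c in content.items()}


def _content_from_json(data: dict) -> dict[str, ChromosomeContent]:
    return {
        n: ChromosomeContent(int(v["dyads"]), int(v["singles"])) for n, v in data.items()
    }


def karyotype_to_json(k: CellKaryotype, seed: int | None = None) -> dict:
    obj = {"stage": k.stage, "content": _content_to_json(k.content)}
    if k.paternal is not None:
        obj["paternal"] = _content_to_json(k.paternal)
    if seed is not None:
        obj["seed"] = seed
    if k.meta:
        obj["meta"] = k.meta
    return obj


def karyotype_from_json(obj: dict) -> CellKaryotype:
    return CellKaryotype(
        stage=obj["stage"],
        content=_content_from_json(obj["content"]),
        paternal=_content_from_json(obj["paternal"]) if "paternal" in obj else None,
        meta=obj.get("meta", {}),
    )


def write_karyotypes_jsonl(
    records: list[tuple[str, CellKaryotype]],
    path: str | Path,
    seed: int | None = None,
) -> None:
    """Write (sample_id, karyotype) records as JSON lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for sample_id, k in records:
            obj = {"sample_id": sample_id, **karyotype_to_json(k, seed=seed)}
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_karyotypes_jsonl(path: str | Path) -> list[tuple[str, CellKaryotype]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        out.append((obj["sample_id"], karyotype_from_json(obj)))
    return out


# ---------------------------------------------------------------------------
# Reference and call tables


def write_reference(
    ref: ReferenceProfile,
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    rows = [
        {"sex": sex, "chrom": n, "proportion": f"{p:.12g}"}
        for sex, props in ref.proportions.items()
        for n, p in props.items()
    ]
    body = (
        f"# mode={ref.mode} n_female={ref.n_female} n_male={ref.n_male}\n"
        + pd.DataFrame(rows).to_csv(sep="\t", index=False)
    )
    _write_with_header(Path(path), body, seed, config)


def read_reference(path: str | Path) -> ReferenceProfile:
    path = Path(path)
    meta = {}
    for raw in path.read_text().splitlines():
        if raw.startswith("# mode="):
            meta = dict(kv.split("=", 1) for kv in raw[2:].split())
            break
    if not meta:
        raise ParseError(f"{path}: missing '# mode=...' header line")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    props: dict[str, dict[str, float]] = {}
    for sex, grp in df.groupby("sex", sort=False):
        props[str(sex)] = dict(zip(grp["chrom"], grp["proportion"].astype(float)))
    return ReferenceProfile(
        proportions=props,
        n_female=int(meta["n_female"]),
        n_male=int(meta["n_male"]),
        mode=meta["mode"],
    )


def write_calls_table(
    results: list[tuple[CopyNumberProfile, AneuploidyCallSet]],
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    """One row per sample x chromosome: ratio, copy number, discrete call."""
    rows = []
    for cnp, calls in results:
        for n in cnp.copy_number:
            rows.append(
                {
                    "sample": cnp.sample_id,
                    "sex_used": cnp.sex_used,
                    "chrom": n,
                    "ratio": f"{cnp.ratios[n]:.6f}",
                    "copy_number": f"{cnp.copy_number[n]:.6f}",
                    "call": calls.calls[n],
                    "complexity": calls.complexity,
                }
            )
    body = pd.DataFrame(rows).to_csv(sep="\t", index=False)
    _write_with_header(Path(path), body, seed, config)


def read_calls_table(
    path: str | Path,
) -> list[tuple[CopyNumberProfile, AneuploidyCallSet]]:
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={"chrom": str})
    out = []
    for sample, grp in df.groupby("sample", sort=False):
        sex = grp["sex_used"].iloc[0]
        ratios = dict(zip(grp["chrom"], grp["ratio"].astype(float)))
        cn = dict(zip(grp["chrom"], grp["copy_number"].astype(float)))
        calls = dict(zip(grp["chrom"], grp["call"]))
        n_aneu = sum(c != "neutral" for c in calls.values())
        cnp = CopyNumberProfile(
            sample_id=str(sample), sex_used=sex, ratios=ratios, copy_number=cn
        )
        callset = AneuploidyCallSet(
            sample_id=str(sample),
            calls=calls,
            n_aneuploid=n_aneu,
            complexity=grp["complexity"].iloc[0],
        )
        out.append((cnp, callset))
    return out
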