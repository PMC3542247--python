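"""Tab-delimited input/output dialects and the parameter file.

All files are plain tab-delimited text with a mandatory header row; the
missing-value code is configurable (default ``NA``). The dialects:

* parameter file: ``KEY = value`` lines, ``;`` or ``#`` comments, keys
  case-insensitive. Mandatory keys: PLOIDY, MAPFUNCTION, CHROMFILE,
  MAPFILE, PEDFILE, FOUNDERFILE, OUTPUT. Optional: MISSING, SEED, TEST
  (number of test-mode meioses). Relative paths are resolved against the
  parameter file's directory.
* chromosome file: columns ``chromosome length centromere prefPairing
  quadrivalents`` (+ optional ``parallel`` and ``pairedCentromeres``);
  lengths and positions in cM; the quadrivalents column takes a fraction
  or the missing code for "natural".
* map file: ``marker chromosome position``.
* pedigree file: ``name parent1 parent2``; founders use the missing code
  for both parents.
* founder file: ``marker`` plus one column ``<founder>_<slot>`` per
  founder homolog, giving the observed allele of that founder haplotype
  at each marker.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genome import (
    NATURAL,
    AlleleAssignment,
    ChromosomeSpec,
    HaploStruct,
    IndividualGenome,
    LocusDef,
    UnsupportedPloidyError,
)
from .population import PedigreeEntry, RealizedGenotypes
from .theory import HALDANE, KOSAMBI

__all__ = [
    "FileFormatError",
    "RunParameters",
    "read_parameter_file",
    "write_parameter_file",
    "read_chromosome_file",
    "read_map_file",
    "read_pedigree_file",
    "read_founder_file",
    "write_outputs",
    "read_haplostruct_file",
]


class FileFormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


_MANDATORY_KEYS = (
    "ploidy",
    "mapfunction",
    "chromfile",
    "mapfile",
    "pedfile",
    "founderfile",
    "output",
)
_KNOWN_KEYS = _MANDATORY_KEYS + ("missing", "seed", "test")


@dataclass
class RunParameters:
    """A validated simulation run definition."""

    ploidy: int
    mapfunction: str
    chromfile: Path
    mapfile: Path
    pedfile: Path
    founderfile: Path
    output_prefix: Path
    missing_code: str = "NA"
    seed: int | None = None
    test_mode: bool = False
    test_meioses: int = 10000


def read_parameter_file(path: str | Path, warn=None) -> RunParameters:
    """Parse and validate a ``KEY = value`` parameter file.

    Unknown keys are reported through ``warn`` (a callable taking one
    string; default: ignore) but are not errors.
    """
    path = Path(path)
    if not path.is_file():
        raise FileFormatError(f"parameter file not found: {path}")
    values: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split(";", 1)[0].split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FileFormatError(f"{path}:{lineno}: expected KEY = value")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if key not in _KNOWN_KEYS:
            if warn is not None:
                warn(f"{path}:{lineno}: unknown key {key!r} ignored")
            continue
        values[key] = value
    for key in _MANDATORY_KEYS:
        if key not in values:
            raise FileFormatError(f"{path}: missing mandatory key {key.upper()}")
    try:
        ploidy = int(values["ploidy"])
    except ValueError:
        raise FileFormatError(f"{path}: PLOIDY must be an integer") from None
    if ploidy not in (2, 4):
        raise UnsupportedPloidyError(f"{path}: PLOIDY must be 2 or 4, got {ploidy}")
    mapfunction = values["mapfunction"].upper()
    if mapfunction not in (HALDANE, KOSAMBI):
        raise FileFormatError(
            f"{path}: MAPFUNCTION must be one of HALDANE, KOSAMBI "
            f"(got {values['mapfunction']!r})"
        )
    base = path.parent

    def _resolve(key: str) -> Path:
        p = Path(values[key])
        return p if p.is_absolute() else base / p

    params = RunParameters(
        ploidy=ploidy,
        mapfunction=mapfunction,
        chromfile=_resolve("chromfile"),
        mapfile=_resolve("mapfile"),
        pedfile=_resolve("pedfile"),
        founderfile=_resolve("founderfile"),
        output_prefix=_resolve("output"),
        missing_code=values.get("missing", "NA"),
        seed=int(values["seed"]) if "seed" in values else None,
        test_mode="test" in values,
        test_meioses=int(values["test"]) if values.get("test") else 10000,
    )
    for attr in ("chromfile", "mapfile", "pedfile", "founderfile"):
        p = getattr(params, attr)
        if not p.is_file():
            raise FileFormatError(f"{path}: {attr.upper()} does not exist: {p}")
    return params


def write_parameter_file(params: RunParameters, path: str | Path) -> None:
    """Write a parameter file that :func:`read_parameter_file` round-trips."""
    lines = [
        f"PLOIDY = {params.ploidy}",
        f"MAPFUNCTION = {params.mapfunction}",
        f"MISSING = {params.missing_code}",
        f"CHROMFILE = {params.chromfile}",
        f"MAPFILE = {params.mapfile}",
        f"PEDFILE = {params.pedfile}",
        f"FOUNDERFILE = {params.founderfile}",
        f"OUTPUT = {params.output_prefix}",
    ]
    if params.seed is not None:
        lines.append(f"SEED = {params.seed}")
    if params.test_mode:
        lines.append(f"TEST = {params.test_meioses}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise FileFormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FileFormatError(f"{path}: empty file (header row required)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {missing}")
    return df


def _float(path, row, column, value) -> float:
    try:
        return float(value)
    except ValueError:
        raise FileFormatError(
            f"{path}: row {row}: column {column!r}: not a number: {value!r}"
        ) from None


def read_chromosome_file(path: str | Path, missing_code: str = "NA") -> list[ChromosomeSpec]:
    """Read chromosome definitions; the quadrivalents column accepts the
    missing code for the natural (pairing-driven) ratio."""
    path = Path(path)
    df = _read_table(path, ["chromosome", "length", "centromere", "prefPairing", "quadrivalents"])
    if len(df) == 0:
        raise FileFormatError(f"{path}: no chromosomes defined")
    specs = []
    seen: set[str] = set()
    for idx, rec in enumerate(df.to_dict("records"), start=2):
        name = rec["chromosome"]
        if name in seen:
            raise FileFormatError(f"{path}: row {idx}: duplicate chromosome {name!r}")
        seen.add(name)
        quad = rec["quadrivalents"]
        quad_fraction = (
            NATURAL if quad == missing_code else _float(path, idx, "quadrivalents", quad)
        )
        parallel = rec.get("parallel", "")
        paired = rec.get("pairedCentromeres", "")
        try:
            specs.append(
                ChromosomeSpec(
                    name=name,
                    length=_float(path, idx, "length", rec["length"]),
                    centromere_pos=_float(path, idx, "centromere", rec["centromere"]),
                    pref_pairing=_float(path, idx, "prefPairing", rec["prefPairing"]),
                    quadrivalent_fraction=quad_fraction,
                    parallel_fraction=(
                        _float(path, idx, "parallel", parallel) if parallel else 0.0
                    ),
                    paired_centromeres=paired == "1",
                )
            )
        except ValueError as exc:
            raise FileFormatError(f"{path}: row {idx}: {exc}") from None
    return specs


def read_map_file(path: str | Path, specs: list[ChromosomeSpec]) -> list[LocusDef]:
    """Read the marker map, validated against the chromosome definitions."""
    path = Path(path)
    df = _read_table(path, ["marker", "chromosome", "position"])
    lengths = {s.name: s.length for s in specs}
    loci = []
    seen: set[str] = set()
    for idx, rec in enumerate(df.to_dict("records"), start=2):
        marker = rec["marker"]
        if marker in seen:
            raise FileFormatError(f"{path}: row {idx}: duplicate marker {marker!r}")
        seen.add(marker)
        chrom = rec["chromosome"]
        if chrom not in lengths:
            raise FileFormatError(
                f"{path}: row {idx}: marker {marker!r} on unknown chromosome {chrom!r}"
            )
        pos = _float(path, idx, "position", rec["position"])
        if not 0.0 <= pos <= lengths[chrom]:
            raise FileFormatError(
                f"{path}: row {idx}: marker {marker!r} at {pos} cM outside "
                f"chromosome {chrom!r} (length {lengths[chrom]} cM)"
            )
        loci.append(LocusDef(name=marker, chromosome=chrom, position=pos))
    return loci


def read_pedigree_file(path: str | Path, missing_code: str = "NA") -> list[PedigreeEntry]:
    """Read the pedigree; founders carry the missing code for both parents."""
    path = Path(path)
    df = _read_table(path, ["name", "parent1", "parent2"])
    entries = []
    for idx, rec in enumerate(df.to_dict("records"), start=2):
        p1 = None if rec["parent1"] == missing_code else rec["parent1"]
        p2 = None if rec["parent2"] == missing_code else rec["parent2"]
        try:
            entries.append(PedigreeEntry(name=rec["name"], parent1=p1, parent2=p2))
        except ValueError as exc:
            raise FileFormatError(f"{path}: row {idx}: {exc}") from None
    return entries


def read_founder_file(
    path: str | Path,
    genetic_map: list[LocusDef],
    founders: list[str],
    ploidy: int,
) -> AlleleAssignment:
    """Read observed alleles per founder homolog.

    Column ``<founder>_<slot>`` maps to founder allele ID
    ``founder_order * ploidy + slot`` (founder order as in the pedigree).
    The reference allele per locus is the first founder's slot-0 allele.
    """
    path = Path(path)
    expected = [f"{name}_{k}" for name in founders for k in range(ploidy)]
    df = _read_table(path, ["marker"] + expected)
    df = df.set_index("marker")
    observed: dict[str, dict[int, str]] = {}
    reference: dict[str, str] = {}
    for locus in genetic_map:
        if locus.name not in df.index:
            raise FileFormatError(f"{path}: marker {locus.name!r} missing")
        row = df.loc[locus.name]
        observed[locus.name] = {
            allele_id: str(row[col]) for allele_id, col in enumerate(expected)
        }
        reference[locus.name] = str(row[expected[0]])
    return AlleleAssignment(observed=observed, reference=reference)


def write_outputs(
    population: dict[str, IndividualGenome],
    realized: RealizedGenotypes,
    prefix: str | Path,
) -> dict[str, Path]:
    """Write the four result tables; returns the paths written.

    ``<prefix>_founderalleles.dat``: founder allele ID per marker and
    homolog slot; ``<prefix>_genotypes.dat``: observed alleles in the same
    layout; ``<prefix>_alleledose.dat``: reference-allele dosage matrix;
    ``<prefix>_haplostruct.dat``: the founder-segment mosaics themselves.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ploidy = realized.ploidy
    slot_cols = [f"{name}_{k}" for name in realized.individuals for k in range(ploidy)]

    def _matrix(source) -> pd.DataFrame:
        rows = []
        for locus in realized.loci:
            per_ind = source[locus.name]
            row = []
            for name in realized.individuals:
                row.extend(per_ind[name])
            rows.append(row)
        return pd.DataFrame(rows, index=[l.name for l in realized.loci], columns=slot_cols)

    paths = {}
    fa = prefix.parent / f"{prefix.name}_founderalleles.dat"
    _matrix(realized.founder).to_csv(fa, sep="\t", index_label="marker")
    paths["founderalleles"] = fa

    gt = prefix.parent / f"{prefix.name}_genotypes.dat"
    _matrix(realized.observed).to_csv(gt, sep="\t", index_label="marker")
    paths["genotypes"] = gt

    ad = prefix.parent / f"{prefix.name}_alleledose.dat"
    realized.dosage.to_csv(ad, sep="\t", index_label="marker")
    paths["alleledose"] = ad

    hs = prefix.parent / f"{prefix.name}_haplostruct.dat"
    with open(hs, "w") as fh:
        fh.write("individual\tchromosome\thomolog\tstarts\talleles\n")
        for name, genome in population.items():
            for chrom, homs in genome.homologs.items():
                for k, h in enumerate(homs):
                    starts = ",".join(repr(s) for s in h.starts)
                    alleles = ",".join(str(a) for a in h.alleles)
                    fh.write(f"{name}\t{chrom}\t{k}\t{starts}\t{alleles}\n")
    paths["haplostruct"] = hs
    return paths


def read_haplostruct_file(path: str | Path) -> dict[str, dict[str, list[HaploStruct]]]:
    """Read back ``<prefix>_haplostruct.dat`` into per-individual mosaics."""
    df = _read_table(path, ["individual", "chromosome", "homolog", "starts", "alleles"])
    out: dict[str, dict[str, list[tuple[int, HaploStruct]]]] = {}
    for rec in df.to_dict("records"):
        starts = [float(s) for s in rec["starts"].split(",")]
        alleles = [int(a) for a in rec["alleles"].split(",")]
        h = HaploStruct.from_arrays(starts, alleles, rec["chromosome"])
        out.setdefault(rec["individual"], {}).setdefault(rec["chromosome"], []).append(
            (int(rec["homolog"]), h)
        )
    return {
        name: {
            chrom: [h for _, h in sorted(items, key=lambda t: t[0])]
            for chrom, items in chroms.items()
        }
        for name, chroms in out.items()
    }
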