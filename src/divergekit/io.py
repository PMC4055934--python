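"""Readers and writers for the pipeline's file formats.

Tabular inputs are comma-separated UTF-8 with a mandatory header row;
genotypes travel as Genepop (2- or 3-digit allele coding).  Parsers reject
malformed rows with row-numbered diagnostics rather than coercing silently,
and read -> write -> read is the identity on every record type.
"""

from __future__ import annotations

import csv
import decimal
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import yaml

from .records import (
    MISSING,
    AnalysisConfig,
    FIDTrial,
    GenotypeTable,
    MorphRecord,
    PredationCounts,
    QuadrateObservation,
    ValidationError,
)

logger = logging.getLogger("divergekit")

__all__ = [
    "FormatError",
    "read_morph_table",
    "write_morph_table",
    "read_quadrate_table",
    "write_quadrate_table",
    "read_fid_table",
    "write_fid_table",
    "read_predation_table",
    "write_predation_table",
    "read_genepop",
    "write_genepop",
    "load_config",
    "round_half_away",
    "format_number",
    "write_report_tables",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the documented format."""


MORPH_COLUMNS = [
    "individual_id", "population", "sex", "year", "body_length_mm",
    "dorsal_area_mm2", "crest_area_mm2", "ventral_area_mm2",
    "prop_fin_coloured", "fin_R", "fin_G", "body_R", "body_G",
]
QUADRATE_COLUMNS = [
    "population", "quadrate_id", "observation_index",
    "n_males", "n_females", "n_juveniles", "exposed_area_m2",
]
FID_COLUMNS = ["population", "sex", "d_start_paces", "d_flee_paces"]
PREDATION_COLUMNS = [
    "population", "n_cat1", "n_cat2", "n_cat3", "n_cat4", "n_cat5",
]


def _open_reader(path, required_columns):
    path = Path(path)
    handle = path.open("r", encoding="utf-8", newline="")
    reader = csv.DictReader(handle)
    header = reader.fieldnames
    if header is None:
        handle.close()
        raise FormatError(f"{path}: empty file, header row required")
    missing = [c for c in required_columns if c not in header]
    if missing:
        handle.close()
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return handle, reader


def _parse_float(value: str, column: str, row_no: int,
                 optional: bool = False) -> Optional[float]:
    value = (value or "").strip()
    if value == "":
        if optional:
            return None
        raise ValidationError(f"row {row_no}: column {column!r} is empty")
    try:
        return float(value)
    except ValueError:
        raise ValidationError(
            f"row {row_no}: column {column!r} is not numeric: {value!r}"
        ) from None


def _parse_int(value: str, column: str, row_no: int) -> int:
    value = (value or "").strip()
    try:
        return int(value)
    except ValueError:
        raise ValidationError(
            f"row {row_no}: column {column!r} is not an integer: {value!r}"
        ) from None


def read_morph_table(path) -> List[MorphRecord]:
    """Parse a per-individual morphometric/colour CSV.

    Female rows must leave ``crest_area_mm2`` blank; a populated value is
    ignored with a logged warning (females have no head crest).
    """
    handle, reader = _open_reader(path, MORPH_COLUMNS)
    records: List[MorphRecord] = []
    try:
        for row_no, row in enumerate(reader, start=2):
            sex = (row["sex"] or "").strip()
            crest_raw = (row.get("crest_area_mm2") or "").strip()
            crest: Optional[float]
            if sex == "F":
                if crest_raw:
                    logger.warning(
                        "%s row %d: crest_area_mm2=%s on a female row ignored",
                        path, row_no, crest_raw,
                    )
                crest = None
            else:
                crest = _parse_float(crest_raw, "crest_area_mm2", row_no,
                                     optional=True)
            try:
                rec = MorphRecord(
                    individual_id=(row["individual_id"] or "").strip(),
                    population=(row["population"] or "").strip(),
                    sex=sex,
                    year=_parse_int(row["year"] or "0", "year", row_no),
                    body_length_mm=_parse_float(
                        row["body_length_mm"], "body_length_mm", row_no),
                    dorsal_area_mm2=_parse_float(
                        row["dorsal_area_mm2"], "dorsal_area_mm2", row_no),
                    crest_area_mm2=crest,
                    ventral_area_mm2=_parse_float(
                        row["ventral_area_mm2"], "ventral_area_mm2", row_no),
                    prop_fin_coloured=_parse_float(
                        row["prop_fin_coloured"], "prop_fin_coloured", row_no,
                        optional=True),
                    fin_R=_parse_float(row["fin_R"], "fin_R", row_no, True),
                    fin_G=_parse_float(row["fin_G"], "fin_G", row_no, True),
                    body_R=_parse_float(row["body_R"], "body_R", row_no, True),
                    body_G=_parse_float(row["body_G"], "body_G", row_no, True),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {row_no}: {exc}") from None
            records.append(rec)
    finally:
        handle.close()
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_morph_table(records: Iterable[MorphRecord], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(MORPH_COLUMNS)
        for r in records:
            writer.writerow([
                r.individual_id, r.population, r.sex, r.year,
                _fmt(r.body_length_mm), _fmt(r.dorsal_area_mm2),
                _fmt(r.crest_area_mm2), _fmt(r.ventral_area_mm2),
                _fmt(r.prop_fin_coloured), _fmt(r.fin_R), _fmt(r.fin_G),
                _fmt(r.body_R), _fmt(r.body_G),
            ])


def read_quadrate_table(path) -> List[QuadrateObservation]:
    handle, reader = _open_reader(path, QUADRATE_COLUMNS)
    out: List[QuadrateObservation] = []
    try:
        for row_no, row in enumerate(reader, start=2):
            try:
                out.append(QuadrateObservation(
                    population=(row["population"] or "").strip(),
                    quadrate_id=(row["quadrate_id"] or "").strip(),
                    observation_index=_parse_int(
                        row["observation_index"], "observation_index", row_no),
                    n_males=_parse_int(row["n_males"], "n_males", row_no),
                    n_females=_parse_int(row["n_females"], "n_females", row_no),
                    n_juveniles=_parse_int(
                        row["n_juveniles"], "n_juveniles", row_no),
                    exposed_area_m2=_parse_float(
                        row["exposed_area_m2"], "exposed_area_m2", row_no),
                ))
            except ValidationError as exc:
                raise ValidationError(f"row {row_no}: {exc}") from None
    finally:
        handle.close()
    return out


def write_quadrate_table(obs: Iterable[QuadrateObservation], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(QUADRATE_COLUMNS)
        for o in obs:
            writer.writerow([
                o.population, o.quadrate_id, o.observation_index,
                o.n_males, o.n_females, o.n_juveniles, _fmt(o.exposed_area_m2),
            ])


def read_fid_table(path) -> List[FIDTrial]:
    handle, reader = _open_reader(path, FID_COLUMNS)
    out: List[FIDTrial] = []
    try:
        for row_no, row in enumerate(reader, start=2):
            try:
                out.append(FIDTrial(
                    population=(row["population"] or "").strip(),
                    sex=(row["sex"] or "").strip(),
                    d_start_paces=_parse_int(
                        row["d_start_paces"], "d_start_paces", row_no),
                    d_flee_paces=_parse_int(
                        row["d_flee_paces"], "d_flee_paces", row_no),
                ))
            except ValidationError as exc:
                raise ValidationError(f"row {row_no}: {exc}") from None
    finally:
        handle.close()
    return out


def write_fid_table(trials: Iterable[FIDTrial], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(FID_COLUMNS)
        for t in trials:
            writer.writerow(
                [t.population, t.sex, t.d_start_paces, t.d_flee_paces])


def read_predation_table(path) -> List[PredationCounts]:
    handle, reader = _open_reader(path, PREDATION_COLUMNS)
    out: List[PredationCounts] = []
    try:
        for row_no, row in enumerate(reader, start=2):
            try:
                out.append(PredationCounts(
                    population=(row["population"] or "").strip(),
                    **{f"n_cat{i}": _parse_int(
                        row[f"n_cat{i}"], f"n_cat{i}", row_no)
                       for i in range(1, 6)},
                ))
            except ValidationError as exc:
                raise ValidationError(f"row {row_no}: {exc}") from None
    finally:
        handle.close()
    return out


def write_predation_table(counts: Iterable[PredationCounts], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(PREDATION_COLUMNS)
        for c in counts:
            writer.writerow([c.population, c.n_cat1, c.n_cat2, c.n_cat3,
                             c.n_cat4, c.n_cat5])


# ---------------------------------------------------------------------------
# Genepop

def read_genepop(path) -> GenotypeTable:
    """Parse a Genepop file (2- or 3-digit allele coding).

    Populations are ordered as encountered and named after the first
    individual label in each ``pop`` block (the Genepop convention); all-zero
    allele strings map to a missing call.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    # line 1 is a free-text title
    loci: List[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # loci may be one per line or comma-separated on one line
        for name in lines[i].replace(",", " ").split():
            loci.append(name)
        i += 1
    if not loci:
        raise FormatError(f"{path}: no locus names before first 'pop'")

    populations: List[str] = []
    individual_pops: List[str] = []
    individual_ids: List[str] = []
    calls: List[List[Optional[Tuple[int, int]]]] = []
    current_pop: Optional[str] = None

    def parse_call(token: str, line_no: int):
        if len(token) == 4:
            width = 2
        elif len(token) == 6:
            width = 3
        else:
            raise FormatError(
                f"{path} line {line_no}: allele string {token!r} has odd "
                "length (expected 4 or 6 digits)"
            )
        a, b = int(token[:width]), int(token[width:])
        if a == 0 and b == 0:
            return MISSING
        if a == 0 or b == 0:
            raise FormatError(
                f"{path} line {line_no}: half-missing call {token!r}"
            )
        return (a, b)

    for line_no in range(i, len(lines)):
        raw = lines[line_no]
        stripped = raw.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            current_pop = None
            continue
        if current_pop is None and "," not in stripped:
            raise FormatError(
                f"{path} line {line_no + 1}: expected 'id , genotypes' line"
            )
        if "," not in stripped:
            raise FormatError(
                f"{path} line {line_no + 1}: individual line lacks ','"
            )
        ind_id, geno_part = stripped.split(",", 1)
        ind_id = ind_id.strip()
        if current_pop is None:
            current_pop = ind_id
            populations.append(current_pop)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise FormatError(
                f"{path} line {line_no + 1}: individual {ind_id!r} has "
                f"{len(tokens)} genotypes, expected {len(loci)}"
            )
        row = [parse_call(tok, line_no + 1) for tok in tokens]
        individual_pops.append(current_pop)
        individual_ids.append(ind_id)
        calls.append(row)

    if not populations:
        raise FormatError(f"{path}: no 'pop' sections found")
    return GenotypeTable(populations, loci, individual_pops, calls,
                         individual_ids)


def write_genepop(table: GenotypeTable, path, title: str = "divergekit",
                  digits: int = 3) -> None:
    """Write a GenotypeTable in Genepop format with *digits*-digit alleles."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    out = [title]
    out.extend(table.loci)
    for pop in table.populations:
        out.append("pop")
        for i in table.population_indices(pop):
            parts = []
            for call in table.calls[i]:
                if call is MISSING:
                    parts.append("0" * (2 * digits))
                else:
                    a, b = call
                    if max(a, b) >= 10 ** digits:
                        raise ValueError(
                            f"allele code {max(a, b)} too wide for "
                            f"{digits}-digit coding"
                        )
                    parts.append(f"{a:0{digits}d}{b:0{digits}d}")
            out.append(f"{pop} , " + " ".join(parts))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Config and reports

def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML mapping; unknown keys rejected."""
    with Path(path).open("r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    valid = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return AnalysisConfig(**data)


def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero (2.5 -> 3, -2.5 -> -3)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    # guard digits absorb binary-float representation noise before the tie
    # decision (e.g. 84.24999999999999 for the decimal quantity 84.25)
    d = decimal.Decimal(repr(float(value))).quantize(
        decimal.Decimal(1).scaleb(-(ndigits + 8)),
        rounding=decimal.ROUND_HALF_EVEN,
    ).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def format_number(value, ndigits: int) -> str:
    if value is None:
        return ""
    return f"{round_half_away(float(value), ndigits):.{ndigits}f}"


def write_report_tables(results: dict, out_dir, config=None,
                        seed=None) -> List[Path]:
    """Emit one CSV per analysis table plus a run manifest.

    ``results`` maps table names to already-shaped pandas DataFrames:
    ``pca_loadings``, ``allometry``, ``dest``, ``model_ranking``, ``mantel``.
    Numbers are rounded half away from zero at a documented precision.
    """
    import pandas as pd  # local import keeps module import light

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    precisions = {
        "pca_loadings": 2,
        "allometry": 2,
        "dest": 5,
        "model_ranking": 2,
        "mantel": 4,
    }
    written: List[Path] = []
    for name, frame in results.items():
        if not isinstance(frame, pd.DataFrame):
            continue
        nd = precisions.get(name, 4)
        rounded = frame.copy()
        for col in rounded.columns:
            if pd.api.types.is_float_dtype(rounded[col]):
                rounded[col] = rounded[col].map(
                    lambda v: format_number(v, nd) if pd.notna(v) else "")
        target = out_dir / f"{name}.csv"
        rounded.to_csv(target, index=False, lineterminator="\n")
        written.append(target)

    manifest = {
        "seed": seed,
        "config": (vars(config).copy() if config is not None else None),
        "tables": [p.name for p in written],
    }
    manifest_path = out_dir / "manifest.yaml"
    with manifest_path.open("w", encoding="utf-8") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    written.append(manifest_path)
    return written
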