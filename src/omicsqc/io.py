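"""Input parsing, validation and sample alignment.

File dialects
-------------
Data tables
    TSV, UTF-8, first column header ``ID`` holding feature identifiers,
    remaining columns one per sample.  Empty cells and the tokens ``NA`` /
    ``NaN`` (case-insensitive) are missing; ``0`` is a value.
Sample annotation
    TSV with header ``sample<TAB>class[<TAB>batch][<TAB>order][<TAB>is_qc]``.
    A missing batch column assigns every sample to batch ``B1``; a missing
    ``is_qc`` column marks no sample as a QC replicate.
Gene sets
    Standard GMT: ``name<TAB>description<TAB>member<TAB>member...``.
Config
    YAML with keys mirroring :class:`~omicsqc.datatypes.EvaluationConfig`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    EvaluationConfig,
    GeneSetCollection,
    GeneSetKind,
    OmicsDataTable,
    ParseError,
    SampleAnnotation,
    Scale,
    ValidationError,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("", "na", "nan")

# heuristic only: log2 intensities above this look like linear-scale values
_LOG2_SUSPICIOUS_MAX = 50.0


def _is_missing_token(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


def read_data_table(path: str | Path, name: str | None = None,
                    scale: Scale | str = Scale.RAW) -> OmicsDataTable:
    """Read one feature-by-sample TSV into a validated table.

    Non-numeric cells that are not recognized missing tokens raise a
    :class:`ValidationError` naming the offending coordinates.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}, line 1: expected ID column plus >=1 sample column")
    sample_ids = [h.strip() for h in header[1:]]
    n_cols = len(header)
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise ParseError(
                f"{path}, line {lineno}: expected {n_cols} fields, got {len(cells)}"
            )
        fid = cells[0].strip()
        if not fid:
            raise ParseError(f"{path}, line {lineno}: empty feature ID")
        row: list[float] = []
        for j, cell in enumerate(cells[1:]):
            if _is_missing_token(cell):
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise ValidationError(
                    f"{path}, line {lineno}: non-numeric value {cell!r} for "
                    f"feature {fid!r}, sample {sample_ids[j]!r}"
                ) from exc
        feature_ids.append(fid)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    if len(set(feature_ids)) != len(feature_ids):
        seen: set[str] = set()
        dups = []
        for f in feature_ids:
            if f in seen:
                dups.append(f)
            seen.add(f)
        raise ValidationError(f"{path}: duplicate feature IDs: {sorted(set(dups))[:5]}")
    frame = pd.DataFrame(rows, index=feature_ids, columns=sample_ids)
    table = OmicsDataTable(name=name, values=frame, scale=scale)
    if table.scale is Scale.LOG2:
        mx = np.nanmax(table.values.to_numpy()) if table.values.notna().any().any() else np.nan
        if np.isfinite(mx) and mx > _LOG2_SUSPICIOUS_MAX:
            logger.warning(
                "table %r declared log2 but max value %.3g > %g; check the scale",
                name, mx, _LOG2_SUSPICIOUS_MAX,
            )
    return table


def write_data_table(table: OmicsDataTable, path: str | Path) -> None:
    """Write a table in the same TSV dialect ``read_data_table`` accepts.

    Finite values round-trip exactly (``repr`` of the float); missing
    entries are written as ``NA``.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("ID\t" + "\t".join(table.sample_ids) + "\n")
        arr = table.values.to_numpy()
        for i, fid in enumerate(table.feature_ids):
            cells = [
                "NA" if np.isnan(x) else repr(float(x)) for x in arr[i]
            ]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def read_sample_annotation(path: str | Path) -> SampleAnnotation:
    """Parse the sample annotation TSV.

    Required columns ``sample`` and ``class``; optional ``batch``, ``order``
    (integer run order) and ``is_qc`` (0/1 or true/false).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample", "class"):
        if col not in df.columns:
            raise ParseError(f"{path}: annotation must contain a {col!r} column")
    samples = df["sample"].str.strip()
    if samples.duplicated().any():
        dups = samples[samples.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample IDs: {dups[:5]}")
    out = pd.DataFrame(index=pd.Index(samples, name="sample"))
    out["class_label"] = df["class"].str.strip().to_numpy()
    if "batch" in df.columns:
        out["batch"] = df["batch"].str.strip().to_numpy()
    else:
        logger.info("%s: no batch column; assigning single batch 'B1'", path)
        out["batch"] = "B1"
    if "order" in df.columns:
        def _parse_order(cell: str) -> float:
            cell = cell.strip()
            if _is_missing_token(cell):
                return np.nan
            try:
                return float(int(cell))
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: run order must be an integer, got {cell!r}"
                ) from exc
        out["order"] = [_parse_order(c) for c in df["order"]]
    else:
        out["order"] = np.nan
    if "is_qc" in df.columns:
        truthy = {"1", "true", "yes", "t", "y"}
        falsy = {"0", "false", "no", "f", "n", ""}
        vals = []
        for cell in df["is_qc"]:
            c = cell.strip().lower()
            if c in truthy:
                vals.append(True)
            elif c in falsy or _is_missing_token(c):
                vals.append(False)
            else:
                raise ValidationError(f"{path}: unrecognized is_qc value {cell!r}")
        out["is_qc"] = vals
    else:
        out["is_qc"] = False
    return SampleAnnotation(out)


def read_gmt(path: str | Path, kind: GeneSetKind | str) -> GeneSetCollection:
    """Parse a GMT gene-set file; the description column is discarded.

    Duplicate members within a set are deduplicated with a logged warning.
    An empty file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}, line {lineno}: GMT line needs name, description and "
                f">=1 member; got {len(fields)} fields"
            )
        name = fields[0].strip()
        members_raw = [m.strip() for m in fields[2:] if m.strip()]
        members = list(dict.fromkeys(members_raw))
        if len(members) != len(members_raw):
            logger.warning(
                "%s, line %d: set %r listed %d duplicate member(s); deduplicated",
                path, lineno, name, len(members_raw) - len(members),
            )
        if not members:
            raise ParseError(f"{path}, line {lineno}: set {name!r} has no members")
        if name in sets:
            raise ValidationError(f"{path}: duplicate set name {name!r}")
        sets[name] = members
    return GeneSetCollection(kind=GeneSetKind(kind), sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write(name + "\t" + collection.kind.value + "\t" + "\t".join(members) + "\n")


def read_config(path: str | Path) -> EvaluationConfig:
    """Load an :class:`EvaluationConfig` from YAML (empty file → defaults)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return EvaluationConfig()
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return EvaluationConfig.from_dict(raw)


def align_tables(
    tables: list[OmicsDataTable],
    annotation: SampleAnnotation,
    min_samples: int = 3,
) -> tuple[list[OmicsDataTable], SampleAnnotation]:
    """Restrict all tables to the common sample set, in annotation order.

    Every table's samples must be annotated; the tables' sample sets are
    intersected (feature sets are left untouched — depth metrics need the
    per-table feature lists).  Alignment is idempotent and fails when fewer
    than *min_samples* samples are shared.
    """
    if not tables:
        raise ValidationError("need at least one data table")
    ann_samples = set(annotation.sample_ids)
    for t in tables:
        extra = set(t.sample_ids) - ann_samples
        if extra:
            missing_from_tab = sorted(ann_samples - set(t.sample_ids))
            raise ValidationError(
                f"table {t.name!r}: samples absent from annotation: "
                f"{sorted(extra)}; annotation samples absent from table: "
                f"{missing_from_tab[:10]}"
            )
    common = set(tables[0].sample_ids)
    for t in tables[1:]:
        common &= set(t.sample_ids)
    if len(common) < min_samples:
        counts = {t.name: t.n_samples for t in tables}
        raise ValidationError(
            f"sample intersection has {len(common)} samples (< {min_samples}); "
            f"per-table sample counts: {counts}"
        )
    ordered = [s for s in annotation.sample_ids if s in common]
    aligned = [t.subset_samples(ordered) for t in tables]
    return aligned, annotation.subset(ordered)
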