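"""Readers and writers for the plain-text interchange formats.

* peak-list CSV/TSV: columns ``sample_id, nucleus, shift_ppm, intensity``
  (header required, UTF-8, one row per peak);
* activity CSV: columns ``sample_id, ic50, units, censored``;
* JCAMP-DX files in peak-table form (``##PEAK TABLE=(XY..XY)``), one file
  per nucleus per sample.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

from .activity import ActivityRecord
from .binning import NUCLEI, PeakList


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# peak-list CSV/TSV

PEAK_COLUMNS = ("sample_id", "nucleus", "shift_ppm", "intensity")


def _dialect_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_peaklists(path) -> list[PeakList]:
    """Read a peak-list CSV/TSV into per-sample :class:`PeakList` objects
    (sample order = first appearance)."""
    path = Path(path)
    delim = _dialect_for(path)
    by_sample: dict[str, list] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not set(PEAK_COLUMNS) <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: header must contain columns {PEAK_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            nucleus = row["nucleus"].strip()
            if nucleus not in NUCLEI:
                raise FormatError(f"{path}:{line_no}: unknown nucleus {nucleus!r}")
            try:
                shift = float(row["shift_ppm"])
                intensity = float(row["intensity"]) if row["intensity"] else 1.0
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
            by_sample.setdefault(row["sample_id"], []).append((nucleus, shift, intensity))
    return [PeakList(sample_id=s, peaks=p) for s, p in by_sample.items()]


def write_peaklists(peaklists, path) -> None:
    path = Path(path)
    delim = _dialect_for(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(PEAK_COLUMNS)
        for pl in peaklists:
            for nucleus, shift, intensity in pl.peaks:
                writer.writerow([pl.sample_id, nucleus, repr(shift), repr(intensity)])


# ---------------------------------------------------------------------------
# activity CSV

ACTIVITY_COLUMNS = ("sample_id", "ic50", "units", "censored")
_TRUE = {"1", "true", "yes", "y"}


def read_activity(path) -> list[ActivityRecord]:
    path = Path(path)
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(ACTIVITY_COLUMNS) <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: header must contain columns {ACTIVITY_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            censored = row["censored"].strip().lower() in _TRUE
            raw = row["ic50"].strip()
            try:
                ic50 = float(raw) if raw else None
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from None
            records.append(
                ActivityRecord(
                    sample_id=row["sample_id"],
                    ic50=ic50,
                    units=row["units"].strip(),
                    censored=censored,
                )
            )
    return records


def write_activity(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ACTIVITY_COLUMNS)
        for r in records:
            writer.writerow(
                [r.sample_id, "" if r.ic50 is None else repr(r.ic50), r.units,
                 "true" if r.censored else "false"]
            )


# ---------------------------------------------------------------------------
# JCAMP-DX peak tables

_JCAMP_NUCLEUS = {"1H": "1H", "^1H": "1H", "H": "1H", "13C": "13C", "^13C": "13C", "C": "13C"}
_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"
_PAIR_RE = re.compile(rf"({_NUM})\s*[, ]\s*({_NUM})")


def read_jcamp(path, sample_id: str | None = None, nucleus: str | None = None) -> PeakList:
    """Read a JCAMP-DX peak-table file (``##PEAKTABLE=`` / ``##PEAK TABLE=``,
    XY..XY form) into a single-nucleus :class:`PeakList`.

    The nucleus is taken from ``##.OBSERVENUCLEUS`` (or ``##NUCLEUS``)
    unless given explicitly; the sample id defaults to ``##TITLE`` or the
    file stem.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8", errors="replace").splitlines()
    title = None
    in_table = False
    pairs: list[tuple[float, float]] = []
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("##"):
            label, _, value = stripped.partition("=")
            label = label[2:].replace(" ", "").upper().lstrip(".")
            value = value.strip()
            if label == "TITLE":
                title = value
            elif label in ("OBSERVENUCLEUS", "NUCLEUS") and nucleus is None:
                nucleus = _JCAMP_NUCLEUS.get(value.lstrip("^").upper(), None)
                if nucleus is None:
                    raise FormatError(f"{path}: unrecognized nucleus {value!r}")
            elif label in ("PEAKTABLE", "PEAKASSIGNMENTS"):
                in_table = True
                continue
            elif label == "END" or in_table:
                in_table = False
            continue
        if in_table and stripped:
            for m in _PAIR_RE.finditer(stripped):
                pairs.append((float(m.group(1)), float(m.group(2))))
    if nucleus is None:
        raise FormatError(f"{path}: nucleus not declared; pass nucleus= explicitly")
    if nucleus not in NUCLEI:
        raise FormatError(f"{path}: unknown nucleus {nucleus!r}")
    sid = sample_id or title or path.stem
    return PeakList(sample_id=sid, peaks=[(nucleus, s, i) for s, i in pairs])


def merge_peaklists(*peaklists: PeakList, sample_id: str | None = None) -> PeakList:
    """Concatenate peak lists (e.g. the proton and carbon JCAMP files of
    one sample) under one sample id."""
    if not peaklists:
        raise FormatError("nothing to merge")
    sid = sample_id or peaklists[0].sample_id
    peaks = [p for pl in peaklists for p in pl.peaks]
    return PeakList(sample_id=sid, peaks=peaks)
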