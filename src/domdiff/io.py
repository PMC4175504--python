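"""Readers and writers for the formats the pipeline touches.

* member metadata: TSV with a header row
  (member_id, pdb, chain, sf_code, class, sequence [, ss, resolution]);
* multiple alignments: gapped FASTA, '-' as the only gap character
  ('.' is rejected — mixed gap dialects hide real format errors);
* coordinates: PDB ATOM records (CA atoms of the first model, altloc ''
  or 'A') or a bare x,y,z-per-line table;
* reports: JSON, UTF-8, sorted keys, NaN/Inf rejected.

A database version on disk is a directory:
  members.tsv, alignments/<code>.fasta, outliers.txt, optional coords/<id>.pdb
"""

from __future__ import annotations

import io as _io
import json
import math
import os
from pathlib import Path
from typing import Union

import numpy as np
from Bio import SeqIO

from .model import (DatabaseVersion, DomainMember, FormatError,
                    ScopClass, Superfamily, ValidationError, degap)

MANDATORY_COLUMNS = ("member_id", "pdb", "chain", "sf_code", "class", "sequence")

Source = Union[str, Path, _io.StringIO]


def _as_text(source: Source) -> str:
    """Accept a path, a Path, raw text containing newlines, or a handle."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if "\n" in source or not os.path.exists(source):
        if "\n" not in source and not os.path.exists(source):
            raise FileNotFoundError(source)
        return source
    return Path(source).read_text()


def read_members_table(source: Source) -> list[DomainMember]:
    """Parse a member metadata TSV.  Malformed rows are reported with their
    line number; a header-only file yields an empty list."""
    text = _as_text(source)
    lines = [ln for ln in text.splitlines()]
    if not lines or not lines[0].strip():
        raise FormatError("members table: missing header row")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in MANDATORY_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"members table: missing mandatory columns {missing}")
    idx = {name: header.index(name) for name in header}
    members: list[DomainMember] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < len(MANDATORY_COLUMNS):
            raise FormatError(f"members table line {lineno}: "
                              f"{len(fields)} fields, expected >= "
                              f"{len(MANDATORY_COLUMNS)}")

        def get(col: str) -> str:
            i = idx.get(col)
            return fields[i].strip() if i is not None and i < len(fields) else ""

        ss = get("ss") or None
        res_text = get("resolution")
        try:
            resolution = float(res_text) if res_text else None
        except ValueError:
            raise FormatError(
                f"members table line {lineno}: bad resolution {res_text!r}")
        try:
            members.append(DomainMember(
                member_id=get("member_id"),
                pdb_code=get("pdb"),
                chain=get("chain"),
                superfamily_code=get("sf_code"),
                scop_class=ScopClass.parse(get("class")),
                sequence=get("sequence"),
                ss_string=ss,
                resolution=resolution,
            ))
        except ValidationError as exc:
            raise ValidationError(f"members table line {lineno}: {exc}") from exc
    return members


def read_alignment_fasta(source: Source) -> dict[str, str]:
    """Parse a gapped FASTA alignment into member_id -> aligned string.

    The member id is the first whitespace-delimited token of each header;
    any description after it is dropped.  All rows must share one length.
    """
    text = _as_text(source)
    records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
    alignment: dict[str, str] = {}
    for rec in records:
        if rec.id in alignment:
            raise FormatError(f"alignment: duplicate id {rec.id!r}")
        row = str(rec.seq)
        if "." in row:
            raise FormatError(
                f"alignment row {rec.id!r}: '.' gaps are not supported "
                f"(use '-')")
        alignment[rec.id] = row
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise FormatError(f"alignment: unequal aligned lengths {sorted(lengths)}")
    return alignment


def write_alignment_fasta(alignment: dict[str, str], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for mid in sorted(alignment):
            fh.write(f">{mid}\n{alignment[mid]}\n")


def read_ca_trace(source: Source) -> np.ndarray:
    """Read an ordered C-alpha trace.

    Accepts PDB-format coordinate records (only CA atoms of the first
    model, altloc blank or 'A', in file order) or a plain whitespace- or
    comma-separated x y z table.  Returns an (n, 3) float array.
    """
    text = _as_text(source)
    lines = text.splitlines()
    is_pdb = any(ln.startswith(("ATOM", "HETATM", "MODEL", "HEADER"))
                 for ln in lines)
    points: list[list[float]] = []
    if is_pdb:
        for ln in lines:
            if ln.startswith("ENDMDL"):
                break  # first model only
            if not ln.startswith("ATOM"):
                continue
            atom_name = ln[12:16].strip()
            altloc = ln[16:17].strip()
            if atom_name != "CA" or altloc not in ("", "A"):
                continue
            try:
                points.append([float(ln[30:38]), float(ln[38:46]),
                               float(ln[46:54])])
            except ValueError:
                raise FormatError(f"bad ATOM coordinate record: {ln!r}")
    else:
        for lineno, ln in enumerate(lines, start=1):
            if not ln.strip():
                continue
            parts = ln.replace(",", " ").split()
            if len(parts) != 3:
                raise FormatError(
                    f"coordinate table line {lineno}: expected 3 fields, "
                    f"got {len(parts)}")
            try:
                points.append([float(p) for p in parts])
            except ValueError:
                raise FormatError(
                    f"coordinate table line {lineno}: non-numeric coordinate")
    return np.array(points, dtype=float).reshape(-1, 3)


def write_ca_trace(trace: np.ndarray, path: Union[str, Path]) -> None:
    """Write a trace as minimal PDB ATOM/CA records."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(np.asarray(trace, dtype=float), start=1):
            fh.write(f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if not math.isfinite(v):
            raise ValueError(f"non-finite value {v!r} in report")
        return v
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, set):
        return sorted(obj)
    return obj


def write_json_report(report, path: Union[str, Path]) -> None:
    """Serialise a report (or list of reports) to JSON with sorted keys.

    Output is deterministic: keys sorted, no NaN/Inf permitted.
    """
    payload = _jsonable(report)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_json_report(path: Union[str, Path], cls=None):
    """Read a JSON report; with ``cls`` given, rebuild via ``cls.from_dict``."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if cls is None:
        return data
    if isinstance(data, list):
        return [cls.from_dict(d) for d in data]
    return cls.from_dict(data)


# ---------------------------------------------------------------------------
# version directories

def write_version_dir(db: DatabaseVersion, root: Union[str, Path],
                      write_coords: bool = True) -> Path:
    """Write a database version as a directory tree (see module docstring)."""
    root = Path(root)
    (root / "alignments").mkdir(parents=True, exist_ok=True)
    rows = ["\t".join(MANDATORY_COLUMNS + ("ss", "resolution"))]
    for code in sorted(db.superfamilies):
        sf = db.superfamilies[code]
        write_alignment_fasta(sf.alignment, root / "alignments" / f"{code}.fasta")
        for m in sf.members:
            rows.append("\t".join([
                m.member_id, m.pdb_code, m.chain, m.superfamily_code,
                m.scop_class.value, m.sequence, m.ss_string or "",
                "" if m.resolution is None else f"{m.resolution:g}"]))
            if write_coords and m.ca_trace is not None:
                (root / "coords").mkdir(exist_ok=True)
                write_ca_trace(m.ca_trace, root / "coords" / f"{m.member_id}.pdb")
    (root / "members.tsv").write_text("\n".join(rows) + "\n")
    (root / "outliers.txt").write_text(
        "".join(f"{mid}\n" for mid in sorted(db.outliers)))
    (root / "label.txt").write_text(db.label + "\n")
    return root


def read_version_dir(root: Union[str, Path]) -> DatabaseVersion:
    """Read a database version directory written by :func:`write_version_dir`."""
    root = Path(root)
    label = (root / "label.txt").read_text().strip() \
        if (root / "label.txt").exists() else root.name
    members = read_members_table(root / "members.tsv")
    coords_dir = root / "coords"
    by_sf: dict[str, list[DomainMember]] = {}
    for m in members:
        if coords_dir.exists():
            pdb_path = coords_dir / f"{m.member_id}.pdb"
            if pdb_path.exists():
                m.ca_trace = read_ca_trace(pdb_path)
                if len(m.ca_trace) != m.length:
                    raise ValidationError(
                        f"{m.member_id}: trace length {len(m.ca_trace)} != "
                        f"sequence length {m.length}")
        by_sf.setdefault(m.superfamily_code, []).append(m)
    superfamilies: dict[str, Superfamily] = {}
    for code, ms in by_sf.items():
        aln_path = root / "alignments" / f"{code}.fasta"
        alignment = read_alignment_fasta(aln_path) if aln_path.exists() else {}
        for m in ms:
            if alignment and m.member_id in alignment:
                if degap(alignment[m.member_id]) != m.sequence:
                    raise ValidationError(
                        f"{m.member_id}: alignment row does not de-gap to "
                        f"its sequence")
        superfamilies[code] = Superfamily(
            code=code, name=code, scop_class=ms[0].scop_class,
            members=ms, alignment=alignment)
    outliers_path = root / "outliers.txt"
    outliers = set(outliers_path.read_text().split()) \
        if outliers_path.exists() else set()
    return DatabaseVersion(label=label, superfamilies=superfamilies,
                           outliers=outliers)
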