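"""Readers and writers for conformations and charge tables.

Two plain-text formats are supported:

* multi-frame XYZ — atom-count line, comment line, then one
  ``element x y z`` line per atom. Metadata rides on the comment line as
  space-separated ``key=value`` pairs; ``frame=<int>`` labels the frame.
* charge tables — delimited text (comma by default) with header columns
  ``frame, atom_index, element, q_singlet, q_triplet, q_quintuplet``,
  one row per (frame, atom). Charges are in units of elementary charge e.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParseError
from .structure import SPIN_STATES, ChargeTable, Structure

CHARGE_COLUMNS = ["frame", "atom_index", "element"] + [
    f"q_{s.label}" for s in SPIN_STATES
]


def read_xyz(path: str | os.PathLike) -> list[Structure]:
    """Read a multi-frame XYZ file.

    The frame id is taken from a ``frame=<int>`` token on the comment line
    when present, else frames are numbered sequentially from 0.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Structure] = []
    pos = 0
    seq = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {pos + 1}: expected an atom count, got "
                f"{lines[pos]!r}"
            ) from None
        if n < 1:
            raise ParseError(f"{path}: line {pos + 1}: invalid atom count {n}")
        if pos + 1 >= len(lines):
            raise ParseError(f"{path}: line {pos + 2}: missing comment line")
        comment = lines[pos + 1]
        frame_id = _parse_frame_id(comment, default=seq)
        elements: list[str] = []
        coords = np.empty((n, 3))
        for k in range(n):
            lineno = pos + 2 + k
            if lineno >= len(lines):
                raise ParseError(
                    f"{path}: line {lineno + 1}: truncated frame "
                    f"(expected {n} atoms)"
                )
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {lineno + 1}: expected 'element x y z'"
                )
            elements.append(parts[0])
            try:
                coords[k] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno + 1}: non-numeric coordinate"
                ) from None
        try:
            frames.append(Structure(tuple(elements), coords, frame_id))
        except DataError as exc:
            raise ParseError(f"{path}: frame starting line {pos + 1}: {exc}")
        pos += 2 + n
        seq += 1
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def _parse_frame_id(comment: str, default: int) -> int:
    for token in comment.split():
        if token.startswith("frame="):
            try:
                return int(token[len("frame="):])
            except ValueError:
                raise ParseError(f"malformed frame token {token!r}") from None
    return default


def write_xyz(structures: Sequence[Structure], path: str | os.PathLike) -> None:
    """Write structures as multi-frame XYZ; comment line carries frame=<id>."""
    if not structures:
        raise DataError("cannot write an empty structure list")
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{s.n_atoms}\n")
            fh.write(f"frame={s.frame_id}\n")
            for el, (x, y, z) in zip(s.elements, s.coords):
                fh.write(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def read_charge_table(path: str | os.PathLike, sep: str = ",") -> list[ChargeTable]:
    """Read a wide-format charge table into one :class:`ChargeTable` per frame."""
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable charge table: {exc}") from exc
    missing = [c for c in CHARGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    qcols = [f"q_{s.label}" for s in SPIN_STATES]
    if df[qcols].isna().any().any():
        raise FormatError(f"{path}: NaN charge values present")
    tables: list[ChargeTable] = []
    for frame_id, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("atom_index")
        tables.append(
            ChargeTable(
                frame_id=int(frame_id),
                atom_index=grp["atom_index"].to_numpy(),
                elements=tuple(grp["element"]),
                charges=grp[qcols].to_numpy(dtype=float),
            )
        )
    first = tables[0].atom_index
    for t in tables[1:]:
        if not np.array_equal(t.atom_index, first):
            raise FormatError(
                f"{path}: frame {t.frame_id} covers different atom indices "
                "than the first frame"
            )
    return tables


def charge_tables_to_frame(tables: Iterable[ChargeTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for k in range(t.n_atoms):
            row = {
                "frame": t.frame_id,
                "atom_index": int(t.atom_index[k]),
                "element": t.elements[k],
            }
            for s_i, s in enumerate(SPIN_STATES):
                row[f"q_{s.label}"] = t.charges[k, s_i]
            rows.append(row)
    return pd.DataFrame(rows, columns=CHARGE_COLUMNS)


def write_charge_table(
    tables: Sequence[ChargeTable], path: str | os.PathLike, sep: str = ","
) -> None:
    """Write charge tables in the wide delimited format (lossless at 1e-9 e)."""
    if not tables:
        raise DataError("cannot write an empty charge table list")
    df = charge_tables_to_frame(tables)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
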