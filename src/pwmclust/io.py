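"""Readers and writers for PWM files in JASPAR, TRANSFAC and plain dialects.

JASPAR and TRANSFAC records are parsed with ``Bio.motifs``; the plain
dialect (an optional ``>name`` header followed by L whitespace-separated
rows of 4 reals in A,C,G,T order, one PWM per file) is defined here and
doubles as the interchange layout for per-family PWM directories.

Values are stored as probabilities.  A matrix whose cells are all
integral with some row sum above 1.5 is treated as a count matrix; the
row sums are retained on the :class:`~pwmclust.pwm.PWM` so that writing
the collection back reproduces the original counts.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import motifs as _bio_motifs

from .pwm import PWM, PWMCollection, PWMError, normalize

DIALECTS = ("jaspar", "transfac", "plain")

#: pseudocount applied when a count matrix is converted to probabilities
NORM_PSEUDOCOUNT = 1e-6


class ParseError(ValueError):
    """Malformed PWM file; message names the file (and line where known)."""


def _looks_like_counts(m: np.ndarray) -> bool:
    return bool(
        np.allclose(m, np.round(m), atol=1e-9) and np.any(m.sum(axis=1) > 1.5)
    )


def _pwm_from_values(name: str, values: np.ndarray, fmt: str) -> PWM:
    if np.any(values < 0):
        raise ParseError(f"negative value in PWM {name!r}")
    counts_total = values.sum(axis=1) if _looks_like_counts(values) else None
    pc = NORM_PSEUDOCOUNT if np.any(values.sum(axis=1) == 0) else 0.0
    return PWM(name, normalize(values, pc), fmt, counts_total)


# ---------------------------------------------------------------------------
# per-dialect parsing

def _parse_bio(text: str, path: Path, dialect: str) -> list[PWM]:
    try:
        records = _bio_motifs.parse(_io.StringIO(text), dialect)
    except Exception as exc:  # Bio raises bare ValueError/KeyError
        raise ParseError(f"{path}: cannot parse as {dialect}: {exc}") from exc
    out = []
    for rec in records:
        if dialect == "transfac":
            name = rec.get("ID") or rec.get("AC") or rec.name or path.stem
        else:
            name = rec.name or rec.matrix_id or path.stem
        values = np.column_stack([rec.counts[b] for b in "ACGT"])
        out.append(_pwm_from_values(str(name), values, dialect))
    if not out:
        raise ParseError(f"{path}: no PWM records found")
    return out


def _parse_plain(text: str, path: Path) -> list[PWM]:
    # one PWM per file is the normal layout; multiple ">name" blocks in one
    # file are accepted so that single-file exports round-trip
    records: list[tuple[str, list[list[float]]]] = []
    name, rows = path.stem, []

    def flush() -> None:
        if rows:
            records.append((name, rows.copy()))
            rows.clear()

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip() or path.stem
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 values per row, got {len(parts)}"
            )
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
    flush()
    if not records:
        raise ParseError(f"{path}: no matrix rows found")
    return [
        _pwm_from_values(nm, np.array(rw, dtype=float), "plain")
        for nm, rw in records
    ]


def sniff_dialect(text: str) -> str:
    """Guess the dialect from leading tokens of the file."""
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            # JASPAR headers are followed by bracketed base rows
            return "jaspar" if "[" in text else "plain"
        first = line.split()[0]
        if first in ("ID", "AC", "P0", "PO", "NA"):
            return "transfac"
        return "plain"
    return "plain"


def read_pwm_file(path, dialect: str = "auto") -> list[PWM]:
    """Parse one file, which may hold several records (JASPAR/TRANSFAC)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if dialect == "auto":
        dialect = sniff_dialect(text)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "plain":
        return _parse_plain(text, path)
    return _parse_bio(text, path, dialect)


def read_pwms(path, dialect: str = "auto") -> PWMCollection:
    """Read a PWM collection from a file or from every file in a directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise ParseError(f"{path}: directory holds no PWM files")
        coll = PWMCollection()
        for f in files:
            for pwm in read_pwm_file(f, dialect):
                coll.add(pwm)
        return coll
    return PWMCollection(read_pwm_file(path, dialect))


# ---------------------------------------------------------------------------
# writing

def _fmt(x: float) -> str:
    if abs(x - round(x)) < 1e-9:
        return str(int(round(x)))
    return f"{x:.12g}"


def _out_values(pwm: PWM) -> np.ndarray:
    c = pwm.counts()
    return c if c is not None else pwm.matrix


def format_jaspar(pwm: PWM) -> str:
    v = _out_values(pwm)
    lines = [f">{pwm.name} {pwm.name}"]
    for j, base in enumerate("ACGT"):
        cells = "  ".join(_fmt(x) for x in v[:, j])
        lines.append(f"{base}  [ {cells} ]")
    return "\n".join(lines) + "\n"


def format_transfac(pwm: PWM) -> str:
    v = _out_values(pwm)
    lines = [f"ID  {pwm.name}", "XX", "P0      A      C      G      T"]
    consensus = pwm.consensus()
    for i, row in enumerate(v, start=1):
        cells = " ".join(f"{_fmt(x):>6}" for x in row)
        lines.append(f"{i:02d} {cells}      {consensus[i - 1]}")
    lines += ["XX", "//"]
    return "\n".join(lines) + "\n"


def format_plain(pwm: PWM) -> str:
    lines = [f">{pwm.name}"]
    for row in pwm.matrix:
        lines.append("\t".join(f"{x:.9f}" for x in row))
    return "\n".join(lines) + "\n"


_FORMATTERS = {
    "jaspar": format_jaspar,
    "transfac": format_transfac,
    "plain": format_plain,
}


def write_pwms(collection, path, dialect: str = "plain") -> None:
    """Write a collection to one multi-record file, or (if ``path`` is an
    existing directory) one file per PWM named ``<name>.<dialect>``."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(collection) == 0:
        raise ValueError("refusing to write an empty collection")
    path = Path(path)
    fmt = _FORMATTERS[dialect]
    if path.is_dir():
        for pwm in collection:
            (path / f"{pwm.name}.{dialect}").write_text(fmt(pwm))
    else:
        path.write_text("".join(fmt(p) for p in collection))
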