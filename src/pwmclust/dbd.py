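"""Uniformly named DNA-binding-domain (DBD) database and PWM partitioning.

Public motif databases disagree on DBD family naming: the same family
appears as "bZIP" or "Basic Leucine Zipper", and subfamily labels (E2A)
are used where others give the parent family (bHLH).  This module builds
a clean, uniformly named TF -> DBD-family table from local snapshot TSVs
of several sources, resolving conflicts by source precedence, and
partitions a PWM collection into per-family buckets before clustering.
TFs absent from every snapshot fall into the ``unknown_dbd`` category.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .pwm import PWMCollection

UNKNOWN_DBD = "unknown_dbd"

#: higher value wins when sources disagree on a TF's family
SOURCE_PRECEDENCE = {"tfclass": 3, "jolma": 2, "jaspar": 1}


def _norm(name: str) -> str:
    """Matching key: uppercase, spaces/hyphens/underscores stripped."""
    return re.sub(r"[\s\-_]+", "", name).upper()


@dataclass(frozen=True)
class DBDRecord:
    tf_symbol: str
    dbd_family: str
    source: str
    raw_name: str


class SynonymTable:
    """Raw DBD name -> canonical family name, plus subfamily rollups."""

    def __init__(self, mapping: dict[str, str], rollups: dict[str, str]):
        self.mapping = {_norm(k): v for k, v in mapping.items()}
        self.rollups = {_norm(k): v for k, v in rollups.items()}
        for target in list(self.rollups.values()):
            self.mapping.setdefault(_norm(target), target)

    @classmethod
    def from_tsv(cls, path) -> "SynonymTable":
        mapping: dict[str, str] = {}
        rollups: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            kind, raw, canonical = parts
            if kind == "synonym":
                mapping[raw] = canonical
            elif kind == "rollup":
                rollups[raw] = canonical
            else:
                raise ValueError(f"{path}:{lineno}: unknown kind {kind!r}")
        return cls(mapping, rollups)

    @classmethod
    def builtin(cls) -> "SynonymTable":
        ref = resources.files("pwmclust.data") / "dbd_synonyms.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def canonicalize(self, raw: str) -> str:
        """Canonical family for a raw DBD name; rollups applied first.
        Unrecognized names keep their original spelling."""
        key = _norm(raw)
        if key in self.rollups:
            return self.rollups[key]
        return self.mapping.get(key, raw)


def read_snapshot(path, source: str) -> list[tuple[str, str]]:
    """Read a (tf_symbol, dbd_name) snapshot TSV; a header row naming the
    columns is optional."""
    rows: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        for rec in csv.reader(fh, delimiter="\t"):
            if not rec or rec[0].startswith("#"):
                continue
            if rec[0].strip().lower() == "tf_symbol":
                continue
            if len(rec) < 2:
                raise ValueError(f"{path}: snapshot rows need 2 columns")
            rows.append((rec[0].strip(), rec[1].strip()))
    return rows


def build_dbd_database(
    sources: Sequence[tuple[str, str]],
    synonyms: Optional[SynonymTable] = None,
) -> list[DBDRecord]:
    """Merge snapshot tables into one record per TF symbol.

    ``sources`` is a list of ``(path, source_tag)`` pairs with tags from
    tfclass / jolma / jaspar.  When sources disagree, the highest-
    precedence source wins; within one source the first row wins.
    """
    synonyms = synonyms or SynonymTable.builtin()
    best: dict[str, DBDRecord] = {}
    for path, tag in sources:
        if tag not in SOURCE_PRECEDENCE:
            raise ValueError(f"unknown source tag {tag!r}")
        for tf, raw in read_snapshot(path, tag):
            symbol = tf.upper()
            if not symbol:
                continue
            family = synonyms.canonicalize(raw)
            rec = DBDRecord(symbol, family, tag, raw)
            prev = best.get(symbol)
            if prev is None or (
                SOURCE_PRECEDENCE[tag] > SOURCE_PRECEDENCE[prev.source]
            ):
                best[symbol] = rec
    return sorted(best.values(), key=lambda r: r.tf_symbol)


def write_dbd_database(records: Iterable[DBDRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_symbol\tdbd_family\tsource\traw_name\n")
        for r in records:
            fh.write(f"{r.tf_symbol}\t{r.dbd_family}\t{r.source}\t{r.raw_name}\n")


def read_dbd_database(path) -> list[DBDRecord]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if lineno == 1 and line.startswith("tf_symbol"):
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        out.append(DBDRecord(*parts))
    return out


def assign_pwms_to_dbd(
    collection: PWMCollection, db: Iterable[DBDRecord]
) -> dict[str, PWMCollection]:
    """Partition a collection into per-family buckets.

    Every PWM lands in exactly one bucket; TFs without a database record
    go to ``unknown_dbd`` — a category, not an error.
    """
    by_symbol = {r.tf_symbol: r.dbd_family for r in db}
    buckets: dict[str, PWMCollection] = {}
    for pwm in collection:
        family = by_symbol.get(pwm.tf_symbol, UNKNOWN_DBD)
        buckets.setdefault(family, PWMCollection()).add(pwm)
    return buckets
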