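"""Readers and writers for census and classification files.

Censuses are stored as versioned JSON with walk counts serialised as decimal
strings — counts overflow 32- and eventually 64-bit integers, and JSON
numbers would round-trip through floats in some readers.  A SHA-256 checksum
of the canonical payload guards against truncated or hand-edited files.
Per-length tables (N, c_N, mean omega^2) are written as CSV for diffability.
"""

from __future__ import annotations

import csv
import hashlib
import json
from fractions import Fraction
from pathlib import Path

from .enumeration import WalkCensus
from .origins import OriginClass

__all__ = [
    "write_census",
    "read_census",
    "write_census_table",
    "write_classification",
]

SCHEMA = "sawtube-census/1"


def _payload(census: WalkCensus) -> dict:
    return {
        "schema": SCHEMA,
        "lattice": census.lattice_name,
        "tube": None if census.tube is None else str(census.tube),
        "origin": list(census.origin),
        "n_max": census.n_max,
        "first_steps": None if census.first_steps is None else list(census.first_steps),
        "counts": {str(n): str(c) for n, c in sorted(census.counts.items())},
        "e2e_hist": {
            str(n): {str(d2): str(c) for d2, c in sorted(h.items())}
            for n, h in sorted(census.e2e_hist.items())
        },
    }


def _checksum(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def write_census(path: str | Path, census: WalkCensus) -> None:
    """Serialise a census to JSON (counts as decimal strings, checksummed)."""
    payload = _payload(census)
    doc = dict(payload, checksum=_checksum(payload))
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_census(path: str | Path) -> WalkCensus:
    """Load a census written by :func:`write_census`, verifying schema and checksum."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != SCHEMA:
        raise ValueError(
            f"unsupported census schema {doc.get('schema')!r}; expected {SCHEMA!r}"
        )
    stored = doc.pop("checksum", None)
    if stored != _checksum(doc):
        raise ValueError(f"census file {path} failed its checksum")
    return WalkCensus(
        lattice_name=doc["lattice"],
        tube=None if doc["tube"] is None else Fraction(doc["tube"]),
        origin=tuple(doc["origin"]),
        n_max=doc["n_max"],
        counts={int(n): int(c) for n, c in doc["counts"].items()},
        e2e_hist={
            int(n): {int(d2): int(c) for d2, c in h.items()}
            for n, h in doc["e2e_hist"].items()
        },
        first_steps=None if doc["first_steps"] is None else tuple(doc["first_steps"]),
    )


def write_census_table(path: str | Path, census: WalkCensus) -> None:
    """CSV table with one row per length: N, c_N, mean squared end-to-end."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["N", "c_N", "mean_sq_e2e"])
        for n in sorted(census.counts):
            w.writerow([n, census.counts[n], float(census.mean_sq_e2e(n))])


def write_classification(path: str | Path, classes: list[OriginClass]) -> None:
    """CSV table of origin classes: type, representative, multiplicity, overlap."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["type", "representative", "multiplicity",
             "overlap_numerator", "overlap_denominator"]
        )
        for c in classes:
            w.writerow(
                [c.type_index, "{} {} {}".format(*c.representative),
                 c.multiplicity, c.overlap.numerator, c.overlap.denominator]
            )
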