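"""Counts-file formats and the shipped experimental fixtures.

A counts file is either JSON (the schema in ``fixtures/counts.schema.json``)
or CSV (``bitstring,count`` header).  The JSON form carries the experiment
id, measurement basis, qubit order, shot total and a provenance string; the
CSV dialect holds the cells only.  Fixtures are the published measurement
tables of the five chip experiments; aggregated families (IV, V) are always
recomputed from the per-run-group fixtures, never stored.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

from .analytics import CountsTable, aggregate
from .core import bitstrings

#: run-group fixture ids (aggregate families IV and V are derived)
FIXTURE_IDS = ("I", "II", "III", "IVa", "IVb", "IVc", "IVd",
               "Va", "Vb", "Vc", "Vd", "Ve", "Vf")


def _validate_payload(payload: dict, path: str) -> None:
    required = {"experiment", "basis", "qubit_order", "shots", "counts"}
    missing = required - payload.keys()
    if missing:
        raise ValueError(f"{path}: missing fields {sorted(missing)}")
    counts = payload["counts"]
    if not isinstance(counts, dict):
        raise ValueError(f"{path}: 'counts' must be an object")
    n_bits = {len(k) for k in counts}
    if len(n_bits) != 1:
        raise ValueError(f"{path}: inconsistent bitstring lengths")
    n = n_bits.pop()
    for b in bitstrings(n):
        if b not in counts:
            raise ValueError(f"{path}: missing bitstring key {b!r}")
    for key, val in counts.items():
        if set(key) - {"0", "1"}:
            raise ValueError(f"{path}: bad bitstring key {key!r}")
        if not isinstance(val, int) or val < 0:
            raise ValueError(f"{path}: count for {key!r} must be a "
                             "non-negative integer")
    if sum(counts.values()) != payload["shots"]:
        raise ValueError(f"{path}: counts sum to {sum(counts.values())}, "
                         f"but shots = {payload['shots']}")


def read_counts(path) -> CountsTable:
    """Read a counts table from a JSON or CSV file."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows or set(rows[0]) != {"bitstring", "count"}:
            raise ValueError(f"{path}: expected header 'bitstring,count'")
        counts = {r["bitstring"]: int(r["count"]) for r in rows}
        return CountsTable(counts, provenance=str(path))
    with open(path) as fh:
        payload = json.load(fh)
    _validate_payload(payload, str(path))
    return CountsTable(payload["counts"], payload["basis"],
                       payload["qubit_order"],
                       payload.get("provenance", str(path)))


def write_counts(table: CountsTable, path, experiment: str = "") -> None:
    """Write a counts table as JSON or CSV (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["bitstring", "count"])
            for b, c in table.counts.items():
                writer.writerow([b, c])
        return
    payload = {
        "experiment": experiment,
        "basis": table.basis,
        "qubit_order": table.qubit_order,
        "shots": table.shots,
        "counts": table.counts,
        "provenance": table.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_fixture(fixture_id: str) -> CountsTable:
    """Load a published measurement table by experiment id.

    Ids ``IV`` and ``V`` return the cell-wise aggregate of their run groups
    (for IV the counts of II contribute as the first unmutated group).
    """
    if fixture_id == "IV":
        parts = ["II", "IVa", "IVb", "IVc", "IVd"]
        return aggregate([load_fixture(p) for p in parts],
                         provenance="aggregate(II+IVa..IVd)")
    if fixture_id == "V":
        parts = ["Va", "Vb", "Vc", "Vd", "Ve", "Vf"]
        return aggregate([load_fixture(p) for p in parts],
                         provenance="aggregate(Va..Vf)")
    if fixture_id not in FIXTURE_IDS:
        raise KeyError(f"unknown fixture id {fixture_id!r}")
    ref = resources.files("qalife") / "fixtures" / f"table_{fixture_id}.json"
    with resources.as_file(ref) as path:
        return read_counts(path)
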