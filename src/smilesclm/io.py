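"""Dataset readers/writers: plain text (one SMILES per line) and CSV."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

from .curation import CurationReport, MoleculeRecord


def read_smiles(path, smiles_column: str = "smiles",
                id_column: str | None = None) -> list[str]:
    """Read SMILES from a .smi/.txt (one per line, optional whitespace-separated
    id ignored) or a .csv with a configurable SMILES column."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise ValueError(
                    f"{path}: no column {smiles_column!r} (has {reader.fieldnames})")
            return [row[smiles_column] for row in reader]
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def write_smiles(path, smiles: Sequence[str]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["smiles"])
            for s in smiles:
                w.writerow([s])
    else:
        with open(path, "w") as fh:
            fh.writelines(s + "\n" for s in smiles)


def write_curation_outputs(stem, records: Sequence[MoleculeRecord],
                           report: CurationReport) -> None:
    """Write ``<stem>.smi`` (accepted canonical SMILES), ``<stem>.rejects.csv``
    and ``<stem>.report.json``."""
    stem = Path(stem)
    write_smiles(stem.with_suffix(".smi"),
                 [r.canonical_smiles for r in records if r.accepted])
    with open(stem.parent / (stem.name + ".rejects.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["raw_smiles", "reject_reason"])
        for r in records:
            if not r.accepted:
                w.writerow([r.raw_smiles, r.reject_reason.value])
    with open(stem.parent / (stem.name + ".report.json"), "w") as fh:
        json.dump({"input_size": report.input_size,
                   "output_size": report.output_size,
                   "counts_per_step": report.counts_per_step}, fh, indent=1)
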