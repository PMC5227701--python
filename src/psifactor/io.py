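"""Plain-text serialization: tab-separated tables, FASTA contexts, YAML
configuration, sample sheets, and input validation.

Junction count tables are a single TSV with one row per event: the event
metadata columns followed by ``inc_<sample>`` and ``skip_<sample>`` count
columns.  The sample sheet is a two-column TSV (sample, condition).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .events import CONDITIONS, JunctionCountTable, SpliceEvent

__all__ = [
    "write_junction_table",
    "read_junction_table",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_fasta",
    "read_fasta",
    "write_config",
    "read_config",
    "validate_inputs",
    "file_sha256",
]

META_COLS = [
    "event_id",
    "gene_id",
    "event_type",
    "chrom",
    "coordinates",
    "strand",
    "inc_norm",
    "skip_norm",
]


def write_junction_table(table: JunctionCountTable, path) -> None:
    rows = []
    for ev in table.events:
        row = {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "chrom": ev.chrom,
            "coordinates": ",".join(map(str, ev.coordinates)),
            "strand": ev.strand,
            "inc_norm": ev.inc_junction_count,
            "skip_norm": ev.skip_junction_count,
        }
        for s in table.samples:
            row[f"inc_{s}"] = int(table.inclusion_counts.loc[ev.event_id, s])
            row[f"skip_{s}"] = int(table.skipping_counts.loc[ev.event_id, s])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_junction_table(path, sample_conditions: dict | None = None) -> JunctionCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = [c[4:] for c in df.columns if c.startswith("inc_") and c != "inc_norm"]
    events = [
        SpliceEvent(
            event_id=r["event_id"],
            gene_id=r["gene_id"],
            event_type=r["event_type"],
            chrom=str(r["chrom"]),
            coordinates=tuple(int(x) for x in str(r["coordinates"]).split(",")),
            strand=r["strand"],
            inc_junction_count=int(r["inc_norm"]),
            skip_junction_count=int(r["skip_norm"]),
        )
        for _, r in df.iterrows()
    ]
    ids = [e.event_id for e in events]
    inc = df[[f"inc_{s}" for s in samples]].copy()
    inc.columns = samples
    inc.index = ids
    skp = df[[f"skip_{s}" for s in samples]].copy()
    skp.columns = samples
    skp.index = ids
    return JunctionCountTable(
        events=events,
        inclusion_counts=inc.astype(int),
        skipping_counts=skp.astype(int),
        sample_conditions=sample_conditions or {},
    )


def write_sample_sheet(sample_conditions: dict, path) -> None:
    pd.DataFrame(
        {"sample": list(sample_conditions), "condition": list(sample_conditions.values())}
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["condition"]))


def write_fasta(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def validate_inputs(
    table: JunctionCountTable | None = None,
    sample_conditions: dict | None = None,
    gene_counts: pd.DataFrame | None = None,
) -> list:
    """Report-only validation: returns a list of violation strings."""
    violations = []
    if sample_conditions is not None:
        present = set(sample_conditions.values())
        for cond in CONDITIONS:
            if cond not in present:
                violations.append(
                    f"incomplete factorial design: missing condition {cond}"
                )
        unknown = present - set(CONDITIONS)
        for cond in sorted(unknown):
            violations.append(f"unknown condition label: {cond}")
    if table is not None:
        ids = table.event_ids
        if len(set(ids)) != len(ids):
            violations.append("duplicate event ids in junction table")
        for name, df in (
            ("inclusion", table.inclusion_counts),
            ("skipping", table.skipping_counts),
        ):
            arr = df.to_numpy()
            if (arr < 0).any():
                violations.append(f"negative {name} counts present")
            if not (arr == arr.astype(int)).all():
                bad = list(zip(*((arr != arr.astype(int)).nonzero())))
                r, c = bad[0]
                violations.append(
                    f"non-integer {name} count at event {df.index[r]},"
                    f" sample {df.columns[c]}"
                )
        if sample_conditions is not None:
            unassigned = [s for s in table.samples if s not in sample_conditions]
            if unassigned:
                violations.append(f"samples without condition: {unassigned}")
    if gene_counts is not None:
        if gene_counts.index.duplicated().any():
            violations.append("duplicate gene ids in gene count table")
        arr = gene_counts.to_numpy()
        if (arr < 0).any():
            violations.append("negative gene counts present")
    return violations
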