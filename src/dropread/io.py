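"""File formats: droplet tables, truth sidecars, fit reports, reads, config.

Droplet tables are plain CSV with header ``index,diameter_um,<channels...>``;
the sequencing dialect uses channels ``ch532,ch594,ch655,ch701`` and the
methylation-plate dialect ``ch1,ch2`` (auto-detected from the header).
References and resolved reads are FASTA (via Biopython).  Configuration is
JSON or YAML mirroring the dataclass field names.  All coordinates in files
are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gc import GCProfile
from .methyl import MethylCall
from .mixture import MixtureFit, OccupancyCall
from .reads import SetRead
from .simulate import DropletRecord, DropletTruth

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_droplet_table",
    "read_droplet_table",
    "write_truth_table",
    "read_truth_table",
    "write_fit_report",
    "read_fit_report",
    "write_calls_table",
    "write_methyl_calls",
    "write_set_read",
    "read_set_read",
    "write_gc_profile",
    "load_config_mapping",
]

SEQ_CHANNELS = ("ch532", "ch594", "ch655", "ch701")
METHYL_CHANNELS = ("ch1", "ch2")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, record: str | None = None) -> str:
    """Read one sequence from a FASTA file (first record unless named)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if record is None:
        return str(records[0].seq).upper()
    for rec in records:
        if rec.id == record:
            return str(rec.seq).upper()
    raise KeyError(f"{path}: no record named {record!r}")


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# droplet tables


def write_droplet_table(path: str | Path, records: Sequence[DropletRecord]) -> None:
    if not records:
        raise ValueError("no records to write")
    channels = records[0].channels
    rows = [
        {"index": r.index, "diameter_um": r.diameter_um, **{c: r.intensity[c] for c in channels}}
        for r in records
    ]
    # %.17g round-trips doubles exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_droplet_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[DropletRecord]:
    """Read a droplet table CSV; dialect auto-detected from the header.

    ``column_map`` optionally renames foreign columns onto the documented
    schema (e.g. for externally deposited tables); it is applied before
    dialect detection.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    cols = set(df.columns)
    for dialect in (SEQ_CHANNELS, METHYL_CHANNELS):
        if set(dialect) <= cols:
            channels = dialect
            break
    else:
        raise ValueError(
            f"{path}: header matches neither the sequencing ({','.join(SEQ_CHANNELS)}) "
            f"nor the methylation ({','.join(METHYL_CHANNELS)}) dialect"
        )
    for col in ("index", "diameter_um"):
        if col not in cols:
            raise ValueError(f"{path}: missing column {col!r}")
    records = []
    for pos, row in df.iterrows():
        try:
            records.append(
                DropletRecord(
                    index=int(row["index"]),
                    diameter_um=float(row["diameter_um"]),
                    intensity={c: float(row[c]) for c in channels},
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {pos + 2}: {exc}") from exc
    return records


def write_truth_table(path: str | Path, truths: Sequence[DropletTruth]) -> None:
    """Truth sidecar: multisets as sorted base strings."""
    rows = [
        {
            "index": t.index,
            "captured": "".join(t.captured),
            "contaminants": "".join(t.contaminants),
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("index", "captured", "contaminants"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# fits and calls


def _fit_to_dict(fit: MixtureFit) -> dict[str, Any]:
    d = dataclasses.asdict(fit)
    d.pop("log_likelihood_path")
    d["crossing_point"] = fit.crossing_point
    return d


def write_fit_report(path: str | Path, fits: Mapping[str, MixtureFit]) -> None:
    payload = {ch: _fit_to_dict(fit) for ch, fit in sorted(fits.items())}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fit_report(path: str | Path) -> dict[str, MixtureFit]:
    payload = json.loads(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(MixtureFit)} - {"log_likelihood_path"}
    return {
        ch: MixtureFit(**{k: v for k, v in d.items() if k in fields})
        for ch, d in payload.items()
    }


def write_calls_table(path: str | Path, calls: Sequence[OccupancyCall]) -> None:
    """Long-format calls CSV: index,channel,occupied,posterior."""
    rows = [
        {"index": c.index, "channel": ch, "occupied": c.occupied[ch], "posterior": c.posterior[ch]}
        for c in calls
        for ch in sorted(c.occupied)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_methyl_calls(path: str | Path, calls: Sequence[MethylCall]) -> None:
    rows = [
        {
            "index": c.index,
            "ch1_posterior": c.ch1_posterior,
            "ch2_posterior": c.ch2_posterior,
            "label": c.label,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reads


def write_set_read(path: str | Path, read: SetRead) -> None:
    """SetRead CSV: position,index,bases (bases as sorted string)."""
    rows = [
        {"position": p, "index": idx, "bases": "".join(d)}
        for p, (idx, d) in enumerate(zip(read.indices, read.droplets))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_set_read(path: str | Path) -> SetRead:
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("position", "index", "bases"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values("position")
    return SetRead(
        droplets=tuple(tuple(str(b)) for b in df["bases"]),
        indices=tuple(int(i) for i in df["index"]),
    )


# ---------------------------------------------------------------------------
# GC profiles


def write_gc_profile(path: str | Path, seqid: str, profile: GCProfile) -> None:
    """BedGraph-style TSV: seqid, start, end, gc (0-based half-open)."""
    n = len(profile.values)
    df = pd.DataFrame(
        {
            "seqid": [seqid] * n,
            "start": np.arange(n),
            "end": np.arange(1, n + 1),
            "gc": profile.values,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration


def load_config_mapping(path: str | Path) -> dict[str, Any]:
    """Load a JSON or YAML configuration mapping (by file suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data
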