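"""File I/O helpers: FASTA clone sets, assay CSV tables, Ct tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from saltphen.methylome import CloneSet, ReferenceRegion

ASSAY_COLUMNS = ("sample_id", "genotype", "tissue", "treatment", "replicate", "assay", "value")
CT_COLUMNS = ("genotype", "tissue", "treatment", "gene_name", "bio_rep", "tech_rep", "ct")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (header, sequence) pairs; the header may carry key=value tags."""
    seq_records = [
        SeqRecord(Seq(seq), id=header.split()[0], description=header)
        for header, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _parse_key_values(description: str) -> dict[str, str]:
    return dict(
        token.split("=", 1) for token in description.split() if "=" in token
    )


def read_reference(path: str | Path) -> ReferenceRegion:
    """Read a single-record reference FASTA; an ``offset=`` header tag is honoured."""
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one reference record")
    rec = records[0]
    tags = _parse_key_values(rec.description)
    return ReferenceRegion(
        region_id=rec.id, sequence=str(rec.seq), offset=int(tags.get("offset", 0))
    )


def read_clone_set(path: str | Path) -> CloneSet:
    """Read one sample's clone FASTA.

    Headers carry the sample key as ``genotype=... tissue=... treatment=...``
    tags; the first record's tags define the sample.
    """
    records = read_fasta(path)
    tags = _parse_key_values(records[0].description)
    return CloneSet(
        genotype=tags.get("genotype", "unknown"),
        tissue=tags.get("tissue", "unknown"),
        treatment=tags.get("treatment", "unknown"),
        clones=tuple(str(r.seq) for r in records),
    )


def write_clone_set(path: str | Path, clone_set: CloneSet) -> None:
    tags = (
        f"genotype={clone_set.genotype} tissue={clone_set.tissue} "
        f"treatment={clone_set.treatment}"
    )
    write_fasta(
        path,
        [(f"clone{idx:02d} {tags}", seq) for idx, seq in enumerate(clone_set.clones, 1)],
    )


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> list[str]:
    return [f"{path}: missing column {c!r}" for c in required if c not in df.columns]


def validate_assay_csv(path: str | Path) -> list[str]:
    """Schema check; returns a list of violations (empty = valid)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - depends on malformed input
        return [f"{path}: unreadable CSV ({exc})"]
    violations = _check_columns(df, [c for c in ASSAY_COLUMNS if c != "sample_id"], path)
    if not violations and not pd.api.types.is_numeric_dtype(df["value"]):
        violations.append(f"{path}: column 'value' is not numeric")
    return violations


def validate_ct_csv(path: str | Path) -> list[str]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        return [f"{path}: unreadable CSV ({exc})"]
    violations = _check_columns(df, CT_COLUMNS, path)
    if not violations and (df["ct"] <= 0).any():
        violations.append(f"{path}: non-positive Ct values")
    return violations


def validate_fasta(path: str | Path) -> list[str]:
    try:
        records = read_fasta(path)
    except Exception as exc:
        return [f"{path}: unreadable FASTA ({exc})"]
    violations = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            violations.append(f"{path}: duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        if not str(rec.seq):
            violations.append(f"{path}: empty sequence for {rec.id!r}")
    return violations


def read_assay_csv(path: str | Path) -> pd.DataFrame:
    violations = validate_assay_csv(path)
    if violations:
        raise ValueError("; ".join(violations))
    return pd.read_csv(path)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    violations = validate_ct_csv(path)
    if violations:
        raise ValueError("; ".join(violations))
    return pd.read_csv(path)


def read_relative_values_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an indicator × genotype relative-value table.

    Expected layout: first column ``indicator``, a ``polarity`` column, and
    one column per genotype.
    """
    df = pd.read_csv(path, sep="\t")
    if "indicator" not in df.columns or "polarity" not in df.columns:
        raise ValueError(f"{path}: need 'indicator' and 'polarity' columns")
    df = df.set_index("indicator")
    polarities = df.pop("polarity").to_dict()
    return df.astype(float), polarities
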