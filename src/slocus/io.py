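"""Readers and writers: FASTA alignments, ms-dialect haplotypes, cross CSVs.

All formats are plain text for desk-scale auditability: FASTA (via
Biopython) for alignments, the classic ms haplotype dialect ("//",
"segsites:", "positions:", 0/1 rows) for binary site matrices, CSV for
cross records and grid results, and YAML/JSON sidecars for linked-group
declarations.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from slocus.crossing import CrossRecord, Genotype
from slocus.ld import SiteMatrix

CROSS_CSV_COLUMNS = [
    "family",
    "maternal_id",
    "paternal_id",
    "maternal_genotype",
    "paternal_genotype",
    "n_pollinations",
    "n_fruit",
]


def read_fasta(path, alignment: bool = True) -> list[SeqRecord]:
    """Read FASTA records, preserving order and description lines.

    With ``alignment=True`` (default) all sequences must have equal length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if alignment and len({len(r.seq) for r in records}) != 1:
        raise ValueError(f"ragged alignment in {path}: sequences differ in length")
    return records


def write_fasta(records_or_sample, path) -> None:
    """Write SeqRecords, (id, seq) pairs, or a SequenceSample to FASTA.

    Simulated samples carry their source class in the description line
    (``sim_0|P``) so the label round-trips through the file.
    """
    if hasattr(records_or_sample, "alignment"):  # SequenceSample
        sample = records_or_sample
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in zip(sample.ids, sample.sequences)
        ]
    else:
        records = []
        for item in records_or_sample:
            if isinstance(item, SeqRecord):
                records.append(item)
            else:
                name, seq = item
                records.append(SeqRecord(Seq(str(seq)), id=str(name), description=""))
    SeqIO.write(records, str(path), "fasta")


def source_labels_from_records(records: Sequence[SeqRecord]) -> list[str]:
    """Parse S/P source labels from ``id|label`` FASTA description lines."""
    labels = []
    for rec in records:
        name = rec.description or rec.id
        labels.append(name.rsplit("|", 1)[-1] if "|" in name else "S")
    return labels


def write_ms(sample_or_sites, path_or_handle, L: int | None = None) -> None:
    """Write a site matrix in the ms haplotype dialect.

    Positions are emitted as site-midpoint fractions of the alignment
    length (6 decimal places, strictly increasing in (0, 1)); rows are 0/1
    haplotype strings.  Accepts a SiteMatrix or anything
    :func:`slocus.ld.segregating_sites` accepts.
    """
    from slocus.ld import segregating_sites

    if isinstance(sample_or_sites, SiteMatrix):
        sites = sample_or_sites
        if L is None:
            L = int(sites.positions[-1]) if sites.positions.size else 1
    else:
        from slocus.ld import _char_matrix

        L = _char_matrix(sample_or_sites).shape[1]
        sites = segregating_sites(sample_or_sites)
    close = False
    if isinstance(path_or_handle, (str, Path)):
        handle: TextIO = open(path_or_handle, "w")
        close = True
    else:
        handle = path_or_handle
    try:
        k = sites.n_sites
        handle.write("//\n")
        handle.write(f"segsites: {k}\n")
        if k:
            fracs = (sites.positions - 0.5) / L
            handle.write("positions: " + " ".join(f"{x:.6f}" for x in fracs) + "\n")
            for row in sites.matrix:
                handle.write("".join(str(int(v)) for v in row) + "\n")
        else:
            handle.write("positions:\n")
        handle.write("\n")
    finally:
        if close:
            handle.close()


def read_ms(path_or_handle, L: int | None = None) -> SiteMatrix:
    """Read the first haplotype block of an ms-dialect file.

    Positions are mapped back to 1-based site indices when ``L`` is given
    (the writer's inverse); otherwise position fractions are kept scaled
    by 10**6 to preserve ordering.
    """
    if isinstance(path_or_handle, (str, Path)):
        text = Path(path_or_handle).read_text()
    else:
        text = path_or_handle.read()
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    try:
        start = lines.index("//")
    except ValueError:
        raise ValueError("no '//' haplotype block found") from None
    seg_line = lines[start + 1]
    if not seg_line.startswith("segsites:"):
        raise ValueError("malformed ms block: missing segsites line")
    k = int(seg_line.split(":", 1)[1])
    if k == 0:
        return SiteMatrix(np.empty((0, 0), dtype=np.int8), np.array([], dtype=np.int64))
    pos_line = lines[start + 2]
    if not pos_line.startswith("positions:"):
        raise ValueError("malformed ms block: missing positions line")
    fracs = np.array([float(x) for x in pos_line.split(":", 1)[1].split()])
    rows = []
    for ln in lines[start + 3 :]:
        if not ln.strip():
            break
        rows.append([int(ch) for ch in ln.strip()])
    matrix = np.array(rows, dtype=np.int8)
    if matrix.shape[1] != k:
        raise ValueError("haplotype rows do not match segsites count")
    if L is not None:
        positions = np.round(fracs * L + 0.5).astype(np.int64)
    else:
        positions = np.round(fracs * 1_000_000).astype(np.int64)
    return SiteMatrix(matrix, positions)


def write_cross_records(records: Sequence[CrossRecord], path) -> None:
    """Write cross records as CSV with '+'-joined genotype fields."""
    rows = [
        {
            "family": r.family,
            "maternal_id": r.maternal_id,
            "paternal_id": r.paternal_id,
            "maternal_genotype": str(r.maternal),
            "paternal_genotype": str(r.paternal),
            "n_pollinations": r.n_pollinations,
            "n_fruit": r.n_fruit,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CROSS_CSV_COLUMNS).to_csv(path, index=False)


def read_cross_records(path) -> list[CrossRecord]:
    """Read cross records from CSV; predicted classes are recomputed."""
    df = pd.read_csv(path, dtype={"family": str, "maternal_id": str, "paternal_id": str})
    missing = set(CROSS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cross-record CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        mat = Genotype.parse(row.maternal_genotype)
        pat = Genotype.parse(row.paternal_genotype)
        records.append(
            CrossRecord(
                family=str(row.family),
                maternal=mat,
                paternal=pat,
                n_pollinations=int(row.n_pollinations),
                n_fruit=int(row.n_fruit),
                maternal_id="" if pd.isna(row.maternal_id) else str(row.maternal_id),
                paternal_id="" if pd.isna(row.paternal_id) else str(row.paternal_id),
                ambiguous_genotype=mat.is_ambiguous or pat.is_ambiguous,
            )
        )
    return records


def write_linked_groups(groups: Mapping[str, frozenset[str]], path) -> None:
    """YAML sidecar mapping each linked-group label to its member products."""
    payload = {label: sorted(members) for label, members in groups.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_linked_groups(path) -> dict[str, frozenset[str]]:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return {str(k): frozenset(map(str, v)) for k, v in payload.items()}


def collapse_products(
    products: Sequence[str], linked_groups: Mapping[str, frozenset[str]]
) -> list[str]:
    """Collapse co-amplified products into haplotype-unit labels.

    Products belonging to a declared linked group are replaced by the
    group label (once); others pass through unchanged.  A partially present
    group is an error, since its members should co-segregate.
    """
    remaining = list(products)
    out: list[str] = []
    for label, members in linked_groups.items():
        present = [p for p in remaining if p in members]
        if not present:
            continue
        if set(present) != set(members):
            raise ValueError(
                f"linked group {label!r} partially present: {sorted(present)}"
            )
        out.append(label)
        remaining = [p for p in remaining if p not in members]
    out.extend(remaining)
    return out


def sample_to_fasta_text(sample) -> str:
    """FASTA text for a simulated sample (convenience for CLI/report use)."""
    buf = _io.StringIO()
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(sample.ids, sample.sequences)
    ]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
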