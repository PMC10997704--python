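"""File formats: chromatogram CSV, spore TSV, profile-matrix TSV, FASTA
alignments and Newick dendrograms.

All writers use locale-independent formatting (decimal point, UTF-8) and are
round-trip stable against their readers.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chromatograms import Chromatogram, PeakCall
from .congruence import AlignedSequenceSet, Dendrogram
from .morphometrics import SporeMeasurementSet

CHROMATOGRAM_HEADER = ["time_min", "a428", "a478", "a519"]

_IUPAC_AMBIGUOUS = set("RYSWKMBDHVU")


def read_chromatogram_csv(path: str | Path, sample_label: str | None = None) -> Chromatogram:
    """Read a `time_min,a428,a478,a519` CSV into a validated Chromatogram.

    Missing columns, non-numeric cells and non-monotone time are rejected
    with row/column diagnostics.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != CHROMATOGRAM_HEADER:
            raise ValueError(
                f"{path.name}: expected header {','.join(CHROMATOGRAM_HEADER)!r}, "
                f"got {header!r}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(f"{path.name}: row {lineno} has {len(row)} fields, expected 4")
            try:
                rows.append([float(x) for x in row])
            except ValueError:
                bad = next(i for i, x in enumerate(row) if not _is_float(x))
                raise ValueError(
                    f"{path.name}: non-numeric value {row[bad]!r} at row {lineno}, "
                    f"column {CHROMATOGRAM_HEADER[bad]!r}"
                ) from None
    data = np.asarray(rows, dtype=float)
    if len(data) >= 2:
        diffs = np.diff(data[:, 0])
        if (diffs <= 0).any():
            bad_row = int(np.flatnonzero(diffs <= 0)[0]) + 3  # +1 header +1 next row +1 base
            raise ValueError(f"{path.name}: time not strictly increasing at row {bad_row}")
    return Chromatogram(
        time=data[:, 0],
        absorbance_428=data[:, 1],
        absorbance_478=data[:, 2],
        absorbance_519=data[:, 3],
        sample_label=sample_label if sample_label is not None else path.stem,
    )


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_chromatogram_csv(c: Chromatogram, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CHROMATOGRAM_HEADER)
        for t, a, b, d in zip(c.time, c.absorbance_428, c.absorbance_478, c.absorbance_519):
            writer.writerow([repr(float(t)), repr(float(a)), repr(float(b)), repr(float(d))])


def write_peak_table(calls: list[PeakCall], path: str | Path) -> None:
    """Write called peaks as TSV: apex_time_min, height, relative_pct, pigment_id, level."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("apex_time_min\theight\trelative_pct\tpigment_id\tlevel\n")
        for c in calls:
            pid = "" if c.pigment_id is None else str(c.pigment_id)
            level = "" if c.level is None else c.level
            fh.write(f"{c.apex_time:.4f}\t{c.height:.6g}\t{c.relative_height:.4f}\t{pid}\t{level}\n")


def read_spore_tsv(path: str | Path) -> list[SporeMeasurementSet]:
    """Read a `species\tlength_um\twidth_um` TSV into per-species measurement sets."""
    df = pd.read_csv(path, sep="\t")
    expected = ["species", "length_um", "width_um"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    return [
        SporeMeasurementSet(
            species=str(sp), lengths=g["length_um"].to_numpy(), widths=g["width_um"].to_numpy()
        )
        for sp, g in df.groupby("species", sort=True)
    ]


def write_spore_tsv(sets: list[SporeMeasurementSet], path: str | Path) -> None:
    rows = [
        {"species": s.species, "length_um": float(l), "width_um": float(w)}
        for s in sets
        for l, w in zip(s.lengths, s.widths)
    ]
    pd.DataFrame(rows, columns=["species", "length_um", "width_um"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta_alignment(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA file.

    Sequences are uppercased; ambiguous IUPAC codes other than N are mapped
    to N.  Records of unequal length or duplicate headers are rejected.
    """
    names: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in names:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        seq = "".join("N" if ch in _IUPAC_AMBIGUOUS else ch for ch in seq)
        names.append(rec.id)
        seqs.append(seq)
    if not names:
        raise ValueError(f"no FASTA records in {path}")
    return AlignedSequenceSet(names=names, sequences=seqs)


def write_fasta_alignment(a: AlignedSequenceSet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, seq in zip(a.names, a.sequences):
            fh.write(f">{name}\n{seq}\n")


def write_profile_matrix_tsv(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index_label="taxon")


def read_profile_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="taxon")


_NEWICK_UNQUOTED_FORBIDDEN = set(" ()[]':;,")


def _newick_label(label: str) -> str:
    if set(label) & _NEWICK_UNQUOTED_FORBIDDEN:
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(t: Dendrogram) -> str:
    """Serialise a dendrogram as Newick with height-difference branch lengths.

    A child hanging at height h_c under a parent at height h_p gets branch
    length h_p - h_c (leaves sit at height 0), so a node's height equals its
    distance to any descendant leaf and re-reading reproduces the cophenetic
    matrix.
    """
    n = t.n_leaves
    children = {n + k: (a, b) for k, (a, b, _) in enumerate(t.merges)}
    height = {i: 0.0 for i in range(n)}
    for k, (_, _, h) in enumerate(t.merges):
        height[n + k] = h

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - height[node]
        if node < n:
            return f"{_newick_label(t.labels[node])}:{bl:.10g}"
        a, b = children[node]
        return f"({render(a, height[node])},{render(b, height[node])}):{bl:.10g}"

    root = n + len(t.merges) - 1
    a, b = children[root]
    h = height[root]
    return f"({render(a, h)},{render(b, h)});"


def write_newick(t: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(t) + "\n", encoding="utf-8")
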