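"""File formats: published-table-layout distance CSV, aligned FASTA, mapping CSV.

The published-table layout packs two matrices into one square table:
nucleotide values below the diagonal with amino-acid values in
parentheses, standard errors above the diagonal (same parenthetical
convention), and ``n/c`` marking pairs whose amino-acid distance was
not computed.  ``read_published_table`` unpacks it into two
:class:`~r2ht.distances.DistanceMatrix` objects; ``write_published_table`` is
its inverse (round-trip safe at 3-decimal precision).

FASTA uses ``-`` as the only gap character; ``N``/``X`` are missing
data.  The mapping CSV carries ``element_id, taxon, degenerate,
fragment`` plus optional ``aligned_start``/``aligned_end`` coverage
columns.
"""

from __future__ import annotations

import importlib.resources
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .distances import DistanceMatrix

_CELL = re.compile(
    r"^\s*(?P<main>[0-9.]+|n/c)\s*(?:\((?P<paren>[0-9.]+|n/c)\))?\s*$"
)


def _parse_cell(cell: str) -> tuple[float | None, float | None]:
    """-> (nt value, aa value); None encodes n/c or absence."""
    m = _CELL.match(cell)
    if not m:
        raise ValueError(f"malformed distance cell {cell!r}")
    main = m.group("main")
    paren = m.group("paren")
    nt = None if main == "n/c" else float(main)
    aa = None if paren in (None, "n/c") else float(paren)
    return nt, aa


def read_published_table(path: str | Path) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Read a published-table-layout CSV into (nt, aa) distance matrices.

    Lower triangle: distances; upper triangle: standard errors; values
    in parentheses: amino-acid counterparts; ``n/c``: not computed.
    Site counts are not printed in such tables and are stored as 0.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    labels = list(df.index)
    if list(df.columns) != labels:
        raise ValueError(
            "asymmetric labels: rows "
            f"{labels} vs columns {list(df.columns)}"
        )
    k = len(labels)
    out = {}
    for mode in ("nt", "aa"):
        out[mode] = {
            "d": np.full((k, k), np.nan),
            "se": np.zeros((k, k)),
            "nc": set(),
        }
        np.fill_diagonal(out[mode]["d"], 0.0)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            cell = df.iloc[i, j]
            if pd.isna(cell) or not str(cell).strip():
                continue
            nt, aa = _parse_cell(str(cell))
            lower = i > j
            for mode, val in (("nt", nt), ("aa", aa)):
                tgt = out[mode]
                if lower:
                    if val is None:
                        tgt["nc"].add(frozenset((labels[i], labels[j])))
                    else:
                        tgt["d"][i, j] = tgt["d"][j, i] = val
                elif val is not None:
                    tgt["se"][i, j] = tgt["se"][j, i] = val
    mats = []
    for mode in ("nt", "aa"):
        tgt = out[mode]
        # pairs never given a distance are not computed
        for i in range(k):
            for j in range(i + 1, k):
                if np.isnan(tgt["d"][i, j]):
                    tgt["nc"].add(frozenset((labels[i], labels[j])))
        mats.append(DistanceMatrix(
            labels=labels,
            d=tgt["d"],
            n_sites=np.zeros((k, k), dtype=int),
            se=tgt["se"],
            mode=mode,
            not_computed=tgt["nc"],
        ))
    return mats[0], mats[1]


def write_published_table(
    nt: DistanceMatrix,
    aa: DistanceMatrix | None,
    path: str | Path,
    decimals: int = 3,
) -> None:
    """Write (nt, aa) matrices in the published-table layout."""
    labels = nt.labels
    if aa is not None and aa.labels != labels:
        raise ValueError("nt and aa label orders differ")
    k = len(labels)

    def fmt(value, nc):
        if nc or value is None or (isinstance(value, float)
                                   and np.isnan(value)):
            return "n/c"
        q = 10 ** decimals
        return f"{np.floor(value * q + 0.5) / q:.{decimals}f}"

    rows = []
    for i in range(k):
        row = []
        for j in range(k):
            if i == j:
                row.append("")
                continue
            pair = frozenset((labels[i], labels[j]))
            if i > j:
                main = fmt(nt.d[i, j], pair in nt.not_computed)
                paren = fmt(aa.d[i, j], pair in aa.not_computed) \
                    if aa is not None else None
            else:
                main = fmt(nt.se[i, j], pair in nt.not_computed)
                paren = fmt(aa.se[i, j], pair in aa.not_computed) \
                    if aa is not None else None
            row.append(main if paren is None else f"{main} ({paren})")
        rows.append(row)
    pd.DataFrame(rows, index=labels, columns=labels).to_csv(
        path, index_label="label"
    )


def load_published_distances() -> tuple[DistanceMatrix, DistanceMatrix]:
    """The bundled published distance table for the nine elements."""
    with importlib.resources.as_file(
        importlib.resources.files("r2ht.data") / "published_distances.csv"
    ) as p:
        return read_published_table(p)


def load_fixture_mapping() -> pd.DataFrame:
    with importlib.resources.as_file(
        importlib.resources.files("r2ht.data") / "elements.csv"
    ) as p:
        return read_mapping(p)


def read_indel_profiles(path: str | Path) -> dict[str, set]:
    """Large-indel profiles CSV -> {element_id: set of StructuralVariant}.

    Columns: element_id, kind, ref_start, ref_end, length_bp.  Elements
    absent from the file have an empty profile.
    """
    from .elements import StructuralVariant

    df = pd.read_csv(path)
    out: dict[str, set] = {}
    for _, row in df.iterrows():
        out.setdefault(row["element_id"], set()).add(StructuralVariant(
            kind=row["kind"],
            ref_start=int(row["ref_start"]),
            ref_end=int(row["ref_end"]),
            length_bp=int(row["length_bp"]),
        ))
    return out


def load_fixture_indel_profiles() -> dict[str, set]:
    with importlib.resources.as_file(
        importlib.resources.files("r2ht.data") / "variants.csv"
    ) as p:
        return read_indel_profiles(p)


def read_mapping(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"element_id", "taxon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mapping CSV lacks columns: {sorted(missing)}")
    for col in ("degenerate", "fragment"):
        if col not in df.columns:
            df[col] = 0
    if df["element_id"].duplicated().any():
        dups = df.loc[df["element_id"].duplicated(), "element_id"]
        raise ValueError(f"duplicate element ids: {sorted(set(dups))}")
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    """Aligned or unaligned FASTA -> ordered {id: sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def coverage_from_mapping(
    mapping: pd.DataFrame,
) -> dict[str, tuple[int, int]]:
    """Per-element coverage intervals, when the columns are present."""
    cov = {}
    if {"aligned_start", "aligned_end"} <= set(mapping.columns):
        for _, row in mapping.iterrows():
            if pd.notna(row["aligned_start"]) and \
                    pd.notna(row["aligned_end"]):
                cov[row["element_id"]] = (
                    int(row["aligned_start"]), int(row["aligned_end"])
                )
    return cov
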