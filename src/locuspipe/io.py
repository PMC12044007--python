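"""Readers and writers for the pipeline's text formats.

TSV summary statistics and count matrices go through pandas; JASPAR-format
position frequency matrices, GMT gene-set files, and FASTA (with a sidecar
SNP table) have small dedicated parsers since the records carried here are
simple and the readers validate the fields the pipeline relies on.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .allelic_motif import ALPHABET

SUMMARY_COLUMNS = ["variant_id", "chrom", "pos", "ref_allele", "alt_allele", "beta", "se", "p"]


class MalformedInputError(ValueError):
    pass


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Typed association records from a TSV; malformed rows are rejected
    with their line numbers."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"missing required column(s): {missing}")
    bad_lines = []
    rows = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            rec = {
                "variant_id": str(row["variant_id"]),
                "chrom": str(row["chrom"]),
                "pos": int(row["pos"]),
                "ref_allele": str(row["ref_allele"]),
                "alt_allele": str(row["alt_allele"]),
                "beta": float(row["beta"]),
                "se": float(row["se"]),
                "p": float(row["p"]),
            }
            if not (0 < rec["p"] <= 1) or rec["se"] <= 0:
                raise ValueError
            rows.append(rec)
        except (ValueError, TypeError):
            bad_lines.append(line_no)
    if bad_lines:
        raise MalformedInputError(f"malformed rows at lines {bad_lines}")
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Dosage matrix TSV, samples as rows, variant ids as header."""
    return pd.read_csv(path, sep="\t")


def write_dosages(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise MalformedInputError("LD matrix must be square")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix, gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise MalformedInputError("negative counts")
    return df


def read_jaspar_pfms(path: str | Path) -> dict[str, np.ndarray]:
    """JASPAR-format PFMs: '>name' lines then four 'A [ ... ]' rows.

    Returns name -> L x 4 count matrix in ACGT order.
    """
    pfms: dict[str, np.ndarray] = {}
    name = None
    rows: dict[str, list[float]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                pfms[name] = _assemble_pfm(name, rows)
            name = line[1:].split()[0]
            rows = {}
        else:
            base = line[0].upper()
            if base not in ALPHABET:
                raise MalformedInputError(f"unexpected PFM row: {line!r}")
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(v) for v in nums]
    if name is not None:
        pfms[name] = _assemble_pfm(name, rows)
    return pfms


def _assemble_pfm(name: str, rows: dict[str, list[float]]) -> np.ndarray:
    if set(rows) != set(ALPHABET):
        raise MalformedInputError(f"PFM {name}: missing base rows")
    lens = {len(v) for v in rows.values()}
    if len(lens) != 1:
        raise MalformedInputError(f"PFM {name}: ragged rows")
    return np.column_stack([rows[b] for b in ALPHABET])


def write_jaspar_pfm(name: str, counts: np.ndarray, path: str | Path) -> None:
    with open(path, "a") as fh:
        fh.write(f">{name}\n")
        for bi, base in enumerate(ALPHABET):
            vals = " ".join(f"{v:g}" for v in counts[:, bi])
            fh.write(f"{base} [ {vals} ]\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line:
            chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Sidecar table for motif scanning: snp_id, sequence_id, position
    (1-based within the sequence), allele1, allele2."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "sequence_id", "position", "allele1", "allele2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInputError(f"missing required column(s): {missing}")
    df["position"] = df["position"].astype(int)
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise MalformedInputError(f"GMT line with < 3 fields: {raw!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
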