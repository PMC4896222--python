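"""Readers and writers for the pipeline's tabular artifacts.

All tables are tab-separated text with a header row, "." as the decimal
mark and no locale handling.  The one non-tabular artifact is the newick
tree.  Every reader validates and rejects malformed input rather than
coercing it; every (write, read) pair is the identity.

Genotypes are held as a pandas DataFrame of nullable integers
(accessions x loci); a cell holds the amplified fragment size in base
pairs, or ``pd.NA`` for a null (non-amplified) allele.  In files the
null allele is the literal token ``NA``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

#: literal token used for the null (non-amplified) allele in files
NULL_SENTINEL = "NA"

TRAITS = ("GL", "GW", "GT", "GL/GW", "TGW")

N_CHROMOSOMES = 12


class FormatError(ValueError):
    """Raised when an input file violates the dialect contract."""


def _check_unique(values, kind: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()]
    if len(dup):
        raise FormatError(f"duplicate {kind} id(s): {', '.join(map(str, dup.unique()))}")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path) -> pd.DataFrame:
    """Read an accession x locus SSR genotype matrix.

    The file has a header row of locus ids, a first column of accession
    ids, and integer fragment sizes (bp) or ``NA`` in the cells.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    _check_unique(raw.index, "accession")
    _check_unique(raw.columns, "locus")
    out = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype="Int64")
    out.index.name = "accession"
    for col in raw.columns:
        cells = raw[col]
        mask = cells != NULL_SENTINEL
        try:
            vals = cells[mask].astype(int)
        except ValueError:
            bad = cells[mask][~cells[mask].str.fullmatch(r"[+-]?\d+")]
            row, val = bad.index[0], bad.iloc[0]
            raise FormatError(
                f"non-integer genotype cell {val!r} at accession {row!r}, locus {col!r}"
            ) from None
        if (vals <= 0).any():
            row = vals.index[vals <= 0][0]
            raise FormatError(f"non-positive allele size at accession {row!r}, locus {col!r}")
        out.loc[mask, col] = vals.values
    return out


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    if genotypes.shape[0] == 0 or genotypes.shape[1] == 0:
        raise FormatError("refusing to write an empty genotype matrix")
    out = genotypes.astype("Int64").astype(object).where(genotypes.notna(), NULL_SENTINEL)
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# marker map


def read_marker_map(path, genotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a locus/chromosome/cM map, sorted by (chromosome, position).

    If ``genotypes`` is given, every genotyped locus must have exactly one
    map row; map loci absent from the genotypes are reported in the
    returned frame's ``attrs['unmatched']`` list.
    """
    mp = pd.read_csv(path, sep="\t", dtype={"locus": str})
    missing = {"locus", "chromosome", "cM"} - set(mp.columns)
    if missing:
        raise FormatError(f"marker map missing column(s): {sorted(missing)}")
    _check_unique(mp["locus"], "locus")
    mp["chromosome"] = mp["chromosome"].astype(int)
    mp["cM"] = mp["cM"].astype(float)
    bad_chrom = ~mp["chromosome"].between(1, N_CHROMOSOMES)
    if bad_chrom.any():
        raise FormatError(
            f"chromosome out of 1-{N_CHROMOSOMES} for locus "
            f"{mp.loc[bad_chrom, 'locus'].iloc[0]!r}"
        )
    if (mp["cM"] < 0).any():
        raise FormatError(
            f"negative cM position for locus {mp.loc[mp['cM'] < 0, 'locus'].iloc[0]!r}"
        )
    mp = mp.sort_values(["chromosome", "cM"], kind="mergesort").reset_index(drop=True)
    if genotypes is not None:
        absent = set(genotypes.columns) - set(mp["locus"])
        if absent:
            raise FormatError(f"genotyped locus missing from map: {sorted(absent)[:5]}")
        mp.attrs["unmatched"] = sorted(set(mp["locus"]) - set(genotypes.columns))
    return mp


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map[["locus", "chromosome", "cM"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype table (accession, trait, year, replicate, value)."""
    ph = pd.read_csv(path, sep="\t", dtype={"accession": str, "trait": str})
    missing = {"accession", "trait", "year", "replicate", "value"} - set(ph.columns)
    if missing:
        raise FormatError(f"phenotype table missing column(s): {sorted(missing)}")
    try:
        ph["value"] = ph["value"].astype(float)
    except ValueError:
        bad = ph[pd.to_numeric(ph["value"], errors="coerce").isna()].iloc[0]
        raise FormatError(
            f"non-numeric phenotype value {bad['value']!r} for accession "
            f"{bad['accession']!r}, trait {bad['trait']!r}"
        ) from None
    ph["year"] = ph["year"].astype(int)
    ph["replicate"] = ph["replicate"].astype(int)
    if (ph["value"] <= 0).any():
        bad = ph[ph["value"] <= 0].iloc[0]
        raise FormatError(
            f"non-positive phenotype value for accession {bad['accession']!r}, "
            f"trait {bad['trait']!r}"
        )
    key = ph[["accession", "trait", "year", "replicate"]]
    if key.duplicated().any():
        bad = key[key.duplicated()].iloc[0]
        raise FormatError(f"duplicate phenotype record: {tuple(bad)}")
    return ph.reset_index(drop=True)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes[["accession", "trait", "year", "replicate", "value"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Q matrix / kinship


def read_q_matrix(path) -> pd.DataFrame:
    q = pd.read_csv(path, sep="\t", index_col=0)
    q.index = q.index.astype(str)
    q.index.name = "accession"
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise FormatError("Q matrix rows must sum to 1")
    return q


def write_q_matrix(q: pd.DataFrame, path) -> None:
    q.to_csv(path, sep="\t", float_format="%.6f")


def read_square_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if list(m.index) != list(m.columns):
        raise FormatError("matrix rows and columns must carry identical ids")
    return m


def write_square_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# newick


def write_newick(tree: skbio.TreeNode, path) -> None:
    """Write a tree in newick form; every leaf must be named."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise FormatError("refusing to write a tree with fewer than 2 leaves")
    for tip in tips:
        if not tip.name:
            raise FormatError("unnamed leaf in tree")
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())


def read_newick(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")
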