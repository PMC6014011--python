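"""Readers and writers for the pipeline's plain-text formats.

Formats: the quant TSV dialect (species, individual, run, peptide, protein,
is_standard, ria), in-frame codon FASTA, newick trees, character tables,
and a generic TSV writer with '#'-prefixed metadata lines and 12
significant-digit floats for reproducible diffs.  Codon and alignment
coordinates are 1-based in all reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, FrameError
from .trees import Phylogeny, TreeError

QUANT_COLUMNS = ["species", "individual", "run", "peptide", "protein",
                 "is_standard", "ria"]


class QuantSchemaError(ValueError):
    pass


def read_quant_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a quant TSV.

    Returns ``(table, bad_rows)``: malformed rows (non-positive or
    non-numeric RIA, missing fields) are collected into ``bad_rows`` with a
    reason rather than silently dropped.  A wrong column set raises
    :class:`QuantSchemaError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise QuantSchemaError(f"{path}: missing columns {missing}")
    df = df[QUANT_COLUMNS]
    reasons = pd.Series("", index=df.index)

    def _parse(x):
        # builtin float() is correctly rounded, unlike pandas' fast parser,
        # so written tables round-trip bit-exactly
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    ria = df["ria"].map(_parse)
    reasons[ria.isna()] = "non_numeric_ria"
    reasons[(ria <= 0).fillna(False)] = "non_positive_ria"
    for c in ["species", "individual", "run", "peptide", "protein"]:
        reasons[df[c].isna() | (df[c].astype(str).str.len() == 0)] = f"missing_{c}"
    bad = reasons != ""
    bad_rows = df[bad].assign(reason=reasons[bad])
    good = df[~bad].copy()
    good["ria"] = ria[~bad]
    good["is_standard"] = good["is_standard"].str.lower().isin(
        ["true", "1", "yes"]
    )
    dup = good.duplicated(["species", "individual", "run", "peptide"])
    if dup.any():
        bad_rows = pd.concat([bad_rows, good[dup].assign(reason="duplicate_key")])
        good = good[~dup]
    return good.reset_index(drop=True), bad_rows.reset_index(drop=True)


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a TSV with '#' metadata lines and stable float formatting.

    Floats are printed with 17 significant digits so that values survive a
    write/read round trip bit-exactly (resumed runs recompute identical
    downstream tables) while remaining byte-reproducible for diffs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def write_quant_table(df: pd.DataFrame, path, metadata=None) -> None:
    write_tsv(df[QUANT_COLUMNS], path, metadata)


def read_codon_fasta(path) -> CodonAlignment:
    """Read an in-frame codon alignment; raises :class:`FrameError` when the
    alignment is out of frame, has unequal lengths, or internal stops."""
    return CodonAlignment.from_fasta(path)


def parse_newick(source) -> Phylogeny:
    """Parse a newick tree from a path or a literal string."""
    text = source
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    return Phylogeny.from_newick(text)


def read_characters(path) -> pd.DataFrame:
    """Species-indexed character table (TSV with a ``species`` column)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "species" not in df.columns:
        raise ValueError(f"{path}: character table needs a 'species' column")
    return df.set_index("species")


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
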