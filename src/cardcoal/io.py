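"""Readers and writers for the formats the pipeline touches.

FASTA for sequences (via Biopython), newick for trees (via dendropy), TSV
for population maps and result tables, JSON for manifests and truth files.
All readers validate and fail with actionable messages; all writer/reader
pairs round-trip losslessly on valid data.
"""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import LocusAlignment

__all__ = [
    "FormatError", "AlignmentError",
    "read_fasta", "write_fasta", "read_newick", "write_newick",
    "read_population_map", "write_population_map", "write_manifest",
]


class FormatError(ValueError):
    """Malformed input file."""


class AlignmentError(FormatError):
    """Sequences do not form a valid alignment."""


def read_fasta(path, **kwargs) -> LocusAlignment:
    """Read an aligned FASTA file into a :class:`LocusAlignment`.

    Case is preserved; A/C/G/T/N and the gap symbol '-' are accepted (other
    IUPAC ambiguity codes are rejected because the pipeline expects phased
    haplotypes).  Extra keyword arguments (pop_map, scaler, ...) are passed
    to the :class:`LocusAlignment` constructor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate sequence ids {dup}")
    seqs = [str(r.seq) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(
            f"{path}: sequences have unequal lengths {sorted(lengths)}"
        )
    try:
        return LocusAlignment(ids=ids, seqs=seqs, **kwargs)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_fasta(aln, path, width: int = 60) -> None:
    """Write records as standard FASTA with 60-column line wrapping."""
    if isinstance(aln, LocusAlignment):
        ids, seqs = aln.ids, aln.seqs
    else:
        ids, seqs = zip(*aln) if aln else ((), ())
    if not ids:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for sid, seq in zip(ids, seqs):
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


def read_newick(source) -> dendropy.Tree:
    """Read a rooted newick tree from a path or a literal string.

    Missing branch lengths are read as ``None`` (absent), never as zero.
    Duplicate tip names and unbalanced parentheses raise :class:`FormatError`.
    """
    text = None
    if isinstance(source, (str, Path)):
        s = str(source)
        if "(" in s and ";" in s:
            text = s
        else:
            p = Path(s)
            if not p.exists():
                raise FileNotFoundError(s)
            text = p.read_text()
    else:
        raise TypeError("source must be a path or newick string")
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in newick input")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as e:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error: {e}") from e
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate tip names in newick input: {dup}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


def read_population_map(path) -> dict:
    """Two-column TSV ``sample<TAB>population`` -> dict."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected 'sample<TAB>population'")
        sample, pop = parts
        if sample in out:
            raise FormatError(f"{path}:{ln}: duplicate sample {sample!r}")
        out[sample] = pop
    if not out:
        raise FormatError(f"{path}: empty population map")
    return out


def write_population_map(pop_map: dict, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_map.items():
            fh.write(f"{sample}\t{pop}\n")


def write_manifest(path, seed: int, config: dict | None = None,
                   extra: dict | None = None) -> dict:
    """Write a run manifest (config echo + seed + versions) as JSON."""
    import cardcoal

    manifest = {
        "seed": int(seed),
        "config": config or {},
        "versions": {
            "cardcoal": cardcoal.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
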