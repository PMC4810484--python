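"""Flat-file formats: FASTA, a documented GFF3 dialect, newick, TSV.

The GFF3 dialect written and read here is the one the synthetic generator
emits: one ``region`` feature per replicon (with ``replicon_type`` and
``Is_circular`` attributes) and one ``CDS`` feature per gene carrying ``ID``
and ``replicon_type``.  GFF3 coordinates are 1-based inclusive on disk and
converted to 0-based half-open in memory; ``gene_index`` is assigned per
replicon by start coordinate (ties broken by end, then id).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

import pandas as pd
from skbio import TreeNode

from .alphabet import AMINO_ACIDS
from .errors import InputError
from .simulate import GenomeRecord, TruthTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "annotation_frame",
    "read_tree",
    "write_tree",
    "write_truth_table",
]

_VALID = set(AMINO_ACIDS + "X")


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Parse a protein FASTA (wrapped or unwrapped) into an ordered mapping.

    Rejects duplicate ids, naming the offender, and malformed headers or
    illegal residues with their line number.
    """
    records: Dict[str, str] = {}
    current: Optional[str] = None
    parts: List[str] = []

    def flush() -> None:
        if current is not None:
            records[current] = "".join(parts)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()
                if not header:
                    raise InputError(f"{path}:{lineno}: empty FASTA header")
                flush()
                current = header[0]
                if current in records:
                    raise InputError(f"{path}:{lineno}: duplicate record id {current!r}")
                parts = []
            else:
                if current is None:
                    raise InputError(f"{path}:{lineno}: sequence before first header")
                bad = set(line.upper()) - _VALID
                if bad:
                    raise InputError(
                        f"{path}:{lineno}: illegal residues {sorted(bad)} in {current!r}"
                    )
                parts.append(line.upper())
    flush()
    return records


def write_fasta(records: Mapping[str, str], path: Union[str, Path], width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def annotation_frame(genome: GenomeRecord) -> pd.DataFrame:
    """In-memory annotation table for one genome (0-based half-open)."""
    rep_type = {r.id: r.replicon_type for r in genome.replicons}
    rows = [
        {
            "gene_id": g.id,
            "replicon_id": g.replicon_id,
            "replicon_type": rep_type[g.replicon_id],
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "gene_index": g.gene_index,
        }
        for g in genome.genes
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "replicon_id", "replicon_type", "start", "end", "strand", "gene_index"],
    )


def write_annotation(genome: GenomeRecord, path: Union[str, Path]) -> Path:
    """Emit the GFF3 dialect (1-based inclusive coordinates)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.id} 1 {rep.length}\n")
        for rep in genome.replicons:
            circ = "true" if rep.circular else "false"
            fh.write(
                f"{rep.id}\tsteromine\tregion\t1\t{rep.length}\t.\t+\t.\t"
                f"ID={rep.id};replicon_type={rep.replicon_type};Is_circular={circ}\n"
            )
        for g in genome.genes:
            fh.write(
                f"{g.replicon_id}\tsteromine\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.id};replicon_type={rep_type_of(genome, g.replicon_id)}\n"
            )
    return path


def rep_type_of(genome: GenomeRecord, replicon_id: str) -> str:
    for r in genome.replicons:
        if r.id == replicon_id:
            return r.replicon_type
    raise InputError(f"unknown replicon {replicon_id!r}")


def _parse_attributes(field: str) -> Dict[str, str]:
    out = {}
    for part in field.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_annotation(path: Union[str, Path]) -> pd.DataFrame:
    """Read the GFF3 dialect into an annotation table.

    Coordinates come back 0-based half-open; ``gene_index`` is assigned per
    replicon by (start, end, id).
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from None
            if end_i < start_i:
                raise InputError(f"{path}:{lineno}: end < start")
            if strand not in "+-":
                raise InputError(f"{path}:{lineno}: unknown strand {strand!r}")
            a = _parse_attributes(attrs)
            if "ID" not in a:
                raise InputError(f"{path}:{lineno}: CDS without ID attribute")
            rows.append(
                {
                    "gene_id": a["ID"],
                    "replicon_id": seqid,
                    "replicon_type": a.get("replicon_type", "chromosome"),
                    "start": start_i - 1,
                    "end": end_i,
                    "strand": strand,
                }
            )
    df = pd.DataFrame(
        rows, columns=["gene_id", "replicon_id", "replicon_type", "start", "end", "strand"]
    )
    df = df.sort_values(["replicon_id", "start", "end", "gene_id"], kind="mergesort")
    df["gene_index"] = df.groupby("replicon_id").cumcount()
    return df.reset_index(drop=True)


def read_tree(path: Union[str, Path]) -> TreeNode:
    return TreeNode.read([Path(path).read_text().strip()])


def write_tree(tree: TreeNode, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(str(tree).strip() + "\n")
    return path


def write_truth_table(truth: TruthTable, path: Union[str, Path]) -> Path:
    rows = []
    for gid in sorted(truth.rows):
        r = truth.rows[gid]
        rows.append(
            {
                "genome_id": gid,
                "is_degrader": int(r.is_degrader),
                "pathways": ",".join(sorted(r.pathways)),
                "n_planted": len(r.planted_loci),
                "clusters": ",".join(sorted(r.cluster_memberships)),
                "plasmid_only": int(r.plasmid_only),
                "hgt_donor": r.hgt_donor or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
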