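"""Reciprocal-best-hit orthology and local-synteny calling.

Ortholog identification follows the two-criterion rule used for the
telomere-binding protein family: (1) the BLASTP hit must have an
E-value below 1e-15, and (2) a reciprocal BLASTP of the hit against
the original proteome must return the query as the top hit. Local
synteny between a focal ortholog pair is then assessed over a window
of k genes (default 13) on each side of the focal gene: a neighbor
counts as conserved when its own ortholog lies on the same
chromosome/scaffold as the focal gene's ortholog. BLAST execution is
upstream; this module consumes tabular (outfmt-6) hit files, so no
sequence database is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "read_blast_tab",
    "best_hits",
    "reciprocal_best_hits",
    "GeneAnnotation",
    "read_annotation",
    "neighborhood",
    "OrthologCall",
    "SyntenyCall",
    "call_synteny",
    "pairwise_identity",
]

#: NCBI BLAST outfmt-6 default column order
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class OrthologCall:
    gene_a: str
    gene_b: str
    evalue_ab: float
    evalue_ba: float
    reciprocal: bool


@dataclass(frozen=True)
class SyntenyCall:
    gene_a: str
    gene_b: str
    window_k: int
    mode: str  # "any_side" | "both_sides"
    conserved_neighbors: tuple  # of (neighbor, ortholog, side)
    n_upstream: int
    n_downstream: int
    verdict: bool


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular (outfmt 6) file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(f"expected >=12 BLAST outfmt-6 columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    return df


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per query: min evalue, ties by max bitscore, then
    lexicographically smallest subject id."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("qseqid", keep="first")


def reciprocal_best_hits(
    ab: pd.DataFrame, ba: pd.DataFrame, evalue_max: float = 1e-15
) -> list[OrthologCall]:
    """Reciprocal best hits between species A and B, gated on E-value.

    A pair (a, b) is called reciprocal iff b is a's best hit, a is b's
    best hit, and both E-values are strictly below ``evalue_max``.
    Symmetric in the two input tables.
    """
    if ab.empty or ba.empty:
        return []
    best_ab = best_hits(ab).set_index("qseqid")
    best_ba = best_hits(ba).set_index("qseqid")
    calls = []
    for a, row in best_ab.iterrows():
        b = row["sseqid"]
        if b not in best_ba.index:
            continue
        back = best_ba.loc[b]
        if back["sseqid"] != a:
            continue
        e_ab, e_ba = float(row["evalue"]), float(back["evalue"])
        calls.append(
            OrthologCall(
                gene_a=str(a),
                gene_b=str(b),
                evalue_ab=e_ab,
                evalue_ba=e_ba,
                reciprocal=(e_ab < evalue_max and e_ba < evalue_max),
            )
        )
    return [c for c in calls if c.reciprocal]


@dataclass
class GeneAnnotation:
    """Gene coordinates for one species, orderable by (scaffold, start)."""

    genes: pd.DataFrame  # columns: id, scaffold, start, end [, strand]

    def __post_init__(self) -> None:
        required = {"id", "scaffold", "start", "end"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.genes["id"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        self.genes = self.genes.sort_values(["scaffold", "start"], kind="mergesort")
        self.genes = self.genes.reset_index(drop=True)
        self._by_id = {g: i for i, g in enumerate(self.genes["id"])}

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_id

    def scaffold_of(self, gene: str) -> str:
        return str(self.genes.iloc[self._by_id[gene]]["scaffold"])

    def _row(self, gene: str) -> int:
        if gene not in self._by_id:
            raise KeyError(f"gene {gene!r} not in annotation")
        return self._by_id[gene]


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a GFF3 (gene features) or a 4/5-column TSV annotation.

    TSV columns: id, scaffold, start, end[, strand] (with or without a
    header naming them). GFF3: 'gene' lines, id from ID= or gene_id.
    """
    path = Path(path)
    text_head = path.open().readline()
    if path.suffix in (".gff", ".gff3") or text_head.startswith("##gff"):
        rows = []
        with path.open() as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                if gid is None:
                    raise ValueError(f"gene line without ID attribute: {line!r}")
                rows.append(
                    {
                        "id": gid, "scaffold": parts[0],
                        "start": int(parts[3]), "end": int(parts[4]),
                        "strand": parts[6],
                    }
                )
        return GeneAnnotation(pd.DataFrame(rows))
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:  # headerless
        df = pd.read_csv(path, sep="\t", header=None)
        names = ["id", "scaffold", "start", "end", "strand"][: df.shape[1]]
        df.columns = names
    return GeneAnnotation(df)


def neighborhood(
    gene: str, ann: GeneAnnotation, k: int = 13
) -> tuple[list[str], list[str]]:
    """Up to ``k`` genes on each side of ``gene`` on its scaffold,
    ordered by start coordinate, truncated at scaffold ends."""
    i = ann._row(gene)
    row = ann.genes.iloc[i]
    scaf = row["scaffold"]
    same = ann.genes[ann.genes["scaffold"] == scaf].reset_index(drop=True)
    pos = int(same.index[same["id"] == gene][0])
    upstream = list(same["id"].iloc[max(0, pos - k): pos])
    downstream = list(same["id"].iloc[pos + 1: pos + 1 + k])
    return upstream, downstream


def call_synteny(
    pair: OrthologCall,
    ann_a: GeneAnnotation,
    ann_b: GeneAnnotation,
    ortholog_map: dict[str, str],
    k: int = 13,
    mode: str = "any_side",
) -> SyntenyCall:
    """Local-synteny verdict for an ortholog pair.

    Neighbors of ``gene_a`` (within k genes per side) whose orthologs
    lie on ``gene_b``'s scaffold are conserved. Verdict: under
    ``any_side``, at least one conserved neighbor anywhere in the
    window; under ``both_sides``, at least one upstream AND one
    downstream.
    """
    if mode not in ("any_side", "both_sides"):
        raise ValueError("mode must be any_side or both_sides")
    if pair.gene_a not in ann_a:
        raise KeyError(f"focal gene {pair.gene_a!r} missing from annotation A")
    if pair.gene_b not in ann_b:
        raise KeyError(f"focal gene {pair.gene_b!r} missing from annotation B")
    target_scaffold = ann_b.scaffold_of(pair.gene_b)
    upstream, downstream = neighborhood(pair.gene_a, ann_a, k=k)
    conserved = []
    n_up = n_down = 0
    for side, neighbors in (("upstream", upstream), ("downstream", downstream)):
        for nb in neighbors:
            ortho = ortholog_map.get(nb)
            if ortho is None or ortho not in ann_b:
                continue
            if ann_b.scaffold_of(ortho) == target_scaffold:
                conserved.append((nb, ortho, side))
                if side == "upstream":
                    n_up += 1
                else:
                    n_down += 1
    verdict = (n_up + n_down) >= 1 if mode == "any_side" else (n_up >= 1 and n_down >= 1)
    return SyntenyCall(
        gene_a=pair.gene_a,
        gene_b=pair.gene_b,
        window_k=k,
        mode=mode,
        conserved_neighbors=tuple(conserved),
        n_upstream=n_up,
        n_downstream=n_down,
        verdict=verdict,
    )


_PROTEIN_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")  # BLOSUM62 alphabet
_DNA_ALPHABET = set("ACGTUNRYSWKMBDHV")


def pairwise_identity(seq1: str, seq2: str, kind: str = "protein") -> float:
    """Percent identity of a global (end-to-end) pairwise alignment.

    Protein alignments use BLOSUM62 with gap open 10 / extend 0.5; DNA
    uses match 5 / mismatch -4 with the same gap penalties. Identity is
    identical aligned positions over the full alignment length, gap
    columns included in the denominator, rounded to one decimal.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if kind not in ("protein", "dna"):
        raise ValueError("kind must be protein or dna")
    s1, s2 = seq1.upper(), seq2.upper()
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    alphabet = _PROTEIN_ALPHABET if kind == "protein" else _DNA_ALPHABET
    for s in (s1, s2):
        bad = set(s) - alphabet
        if bad:
            raise ValueError(f"invalid {kind} characters: {sorted(bad)}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if kind == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = 5.0
        aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5

    aln = aligner.align(s1, s2)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return round(100.0 * identical / len(a_row), 1)
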