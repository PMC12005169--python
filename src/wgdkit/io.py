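"""Readers and writers for the pipeline's file formats.

FASTA via Biopython; GFF3 gene models (1-based inclusive on disk, 0-based
half-open in memory); 12-column BLAST-style tabular hits; TSV/BED/JSON
stage outputs. Internal coordinates are converted at the boundary only.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, GeneHit, assign_ranks

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models

def write_gff3(genes: list[GeneModel], path: str | Path,
               source: str = "wgdkit") -> None:
    """Emit gene + CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.start, g.gene_id)):
            start1, end1 = g.start + 1, g.end  # 0-based half-open -> GFF3
            fh.write(
                f"{g.scaffold}\t{source}\tgene\t{start1}\t{end1}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.scaffold}\t{source}\tCDS\t{start1}\t{end1}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}\n"
            )


def load_gene_models(fasta_path: str | Path,
                     gff3_path: str | Path) -> list[GeneModel]:
    """Build gene models from a genome FASTA + GFF3 (parsed with gffutils).

    CDS features are grouped per gene (through mRNA parents when present;
    when a gene has several mRNAs the one with the longest total CDS wins),
    their sequence cut from the scaffold, reverse-complemented on the minus
    strand. A CDS whose length is not a multiple of 3 is kept for
    order-based analyses but flagged invalid for Ks work. Ranks are the
    per-scaffold ordinal of gene starts.
    """
    import gffutils

    scaffolds = read_fasta(fasta_path)
    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique",
                            keep_order=True)

    out: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in scaffolds:
            raise ValueError(
                f"gene {gene.id} on scaffold {gene.seqid!r} absent from FASTA"
            )
        # CDS attached directly to the gene or through each mRNA
        candidates: list[list] = []
        direct = [f for f in db.children(gene, featuretype="CDS", level=1)]
        if direct:
            candidates.append(direct)
        for mrna in db.children(gene, featuretype="mRNA", level=1):
            parts = list(db.children(mrna, featuretype="CDS", level=1))
            if parts:
                candidates.append(parts)
        cds_seq = ""
        if candidates:
            parts = max(candidates,
                        key=lambda ps: sum(f.end - f.start + 1 for f in ps))
            for f in parts:
                if f.seqid not in scaffolds:
                    raise ValueError(
                        f"CDS {f.id} on scaffold {f.seqid!r} absent from FASTA"
                    )
            parts = sorted(parts, key=lambda f: f.start)
            seq = "".join(scaffolds[f.seqid][f.start - 1:f.end]
                          for f in parts)
            if gene.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            cds_seq = seq
        out.append(GeneModel(
            gene_id=gene.id, scaffold=gene.seqid, rank=-1,
            start=gene.start - 1, end=gene.end,
            strand=gene.strand if gene.strand in "+-" else "+",
            cds=cds_seq, cds_valid=bool(cds_seq) and len(cds_seq) % 3 == 0,
        ))
    assign_ranks(out)
    out.sort(key=lambda g: (g.scaffold, g.rank))
    return out


# ---------------------------------------------------------------------------
# BLAST-style tabular hits

def load_hit_table(
    path: str | Path,
    evalue_max: float = 1e-10,
    top_n: int = 5,
) -> list[GeneHit]:
    """Read 12-column tabular hits and reduce to one record per pair.

    Self-hits are dropped, the e-value filter applied, each query keeps its
    ``top_n`` best non-self subjects by bitscore, and finally one best
    record (max bitscore) is kept per unordered pair.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            try:
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            rows.append((cols[0], cols[1], evalue, bitscore))

    rows = [r for r in rows if r[0] != r[1] and r[2] <= evalue_max]
    by_query: dict[str, list] = {}
    for r in rows:
        by_query.setdefault(r[0], []).append(r)
    kept = []
    for q in sorted(by_query):
        qrows = sorted(by_query[q], key=lambda r: (-r[3], r[1]))
        kept.extend(qrows[:top_n])
    best: dict[frozenset, tuple] = {}
    for q, s, ev, bs in kept:
        key = frozenset((q, s))
        if key not in best or bs > best[key][3]:
            best[key] = (q, s, ev, bs)
    return [GeneHit(q, s, score=bs, evalue=ev)
            for q, s, ev, bs in sorted(best.values())]


def write_hit_table(hits: list[GeneHit], path: str | Path) -> None:
    """Write hits back out as minimal 12-column tabular records."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t100.0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:g}\t{h.score:g}\n"
            )


# ---------------------------------------------------------------------------
# stage outputs

def write_blocks_tsv(blocks, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\tscaffold_a\tscaffold_b\torientation\t"
                 "n_anchors\tchain_score\tanchors\n")
        for b in blocks:
            anchors = ";".join(f"{a.gene_a}|{a.gene_b}" for a in b.anchors)
            fh.write(f"{b.block_id}\t{b.scaffold_a}\t{b.scaffold_b}\t"
                     f"{b.orientation}\t{len(b.anchors)}\t{b.chain_score:g}\t"
                     f"{anchors}\n")


def write_pairs_tsv(pairs, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tmode\tblock_id\n")
        for p in pairs:
            bid = "" if p.block_id is None else p.block_id
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.mode}\t{bid}\n")


def write_windows_bed(windows, path: str | Path) -> None:
    """Retained telomeric windows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for w in windows:
            if w.retained:
                fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\t"
                         f"telomere_fwd{w.fwd_count}_rev{w.rev_count}\n")


def write_contig_status_tsv(statuses, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tclassification\tfive_prime\tthree_prime\n")
        for s in statuses:
            fh.write(f"{s.scaffold}\t{s.classification}\t"
                     f"{int(s.five_prime)}\t{int(s.three_prime)}\n")


def write_fractionation_tsv(windows, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_scaffold\twindow\tn_genes\thomoeolog_1\thomoeolog_2\t"
                 "retention_1\tretention_2\ttruncated\n")
        for w in windows:
            fh.write(f"{w.ref_scaffold}\t{w.index}\t{w.n_genes}\t"
                     f"{w.homoeolog_1}\t{w.homoeolog_2}\t"
                     f"{w.retention_1:.2f}\t{w.retention_2:.2f}\t"
                     f"{int(w.truncated)}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_pangene_long_tsv(path: str | Path,
                          species_order: list[str]) -> pd.DataFrame:
    """Long-format pangene table (pangene, species, gene) -> wide counts."""
    df = pd.read_csv(path, sep="\t", names=["pangene", "species", "gene"],
                     header=0)
    wide = (df.groupby(["pangene", "species"]).size()
              .unstack(fill_value=0))
    for sp in species_order:
        if sp not in wide:
            wide[sp] = 0
    return wide[species_order].reset_index()
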