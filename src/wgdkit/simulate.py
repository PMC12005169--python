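"""Synthetic four-species clade with a shared whole-genome duplication.

The simulator produces genomes for two outgroup species ("out1", "out2")
that never duplicated and two ingroup species ("ingA", "ingB") that share a
WGD, together with a complete truth log, so that every downstream stage
(duplicate classification, Ks estimation, peak fitting, dating, telomere
scanning, fractionation and retention analyses) has a parameter-recovery
test against known event times.

Model
-----
* An ancestral genome of ``n_genes`` genes laid out in order over
  ``n_chromosomes`` chromosomes.
* Sequence evolution is a per-site Poisson substitution process. Expected
  pairwise Ks between two sequences separated by ``t`` My of total
  divergence on both branches is ``2 * syn_rate * t``.
* By default every codon is drawn from families whose third position is
  four-fold degenerate (Ala/Gly/Val/Pro/Thr/Leu/Arg/Ser CTN-type families),
  so third positions are exactly synonymous sites and first/second positions
  exactly nonsynonymous — closed-form expectations for tests. A flag allows
  arbitrary sense codons, in which case site classification is taken from
  the starting codon and is approximate.
* Tree: ((ingA, ingB), (out1, out2)); the root and the outgroup split sit at
  ``speciation_ages[0]``, the ingroup split at ``speciation_ages[1]``. The
  WGD happens on the ingroup stem when ``wgd_age > ingroup split`` (the
  shared-WGD scenario, the default) and independently in each ingroup
  lineage otherwise. ``wgd_age=None`` disables the WGD (negative control).
* Post-WGD fractionation: each ingroup species loses one homoeolog of a
  gene with probability ``loss_prob``; the lost copy is on subgenome B with
  probability ``loss_bias`` (0.5 = unbiased).
* Tandem duplicates arise per retained gene copy with probability
  ``tandem_prob`` and are inserted adjacent to their parent.
* Perfect telomere arrays ((TTTAGGG)n at the 5' end, reverse complement at
  the 3' end) are planted on every chromosome.

All randomness flows from one ``numpy`` SeedSequence derived from
``SimConfig.seed``; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .kaks import CODON_TO_AA, STOP_CODONS, InvalidCdsError
from .models import GeneModel, GeneHit, assign_ranks

TELOMERE_UNIT = "TTTAGGG"
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

# Codon families whose third position is four-fold degenerate; restricting
# the ancestral CDS (and substitutions) to these 32 codons makes synonymous
# site counts exact: 1 synonymous + 2 nonsynonymous sites per codon.
FOURFOLD_PREFIXES = ("GC", "GG", "GT", "CC", "AC", "CT", "CG", "TC")
FOURFOLD_CODONS = tuple(p + b for p in FOURFOLD_PREFIXES for b in _BASES)
_FOURFOLD_SET = frozenset(FOURFOLD_CODONS)

SPECIES = ("out1", "out2", "ingA", "ingB")
OUTGROUPS = ("out1", "out2")
INGROUPS = ("ingA", "ingB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Knobs of the clade simulation; ages in My, rates per site per My."""

    n_genes: int = 200
    n_chromosomes: int = 2
    codon_length: int = 150
    wgd_age: float | None = 7.4
    speciation_ages: tuple[float, float] = (20.0, 3.0)  # (outgroup, ingroup)
    syn_rate: float = 0.012
    ka_ks_ratio: float = 0.2  # nonsynonymous rate = ratio * syn_rate
    loss_prob: float = 0.2
    loss_bias: float = 0.5
    tandem_prob: float = 0.02
    tandem_age: float = 1.0
    telomere_repeats_per_end: int = 30
    intergenic_len: int = 60
    fourfold_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < self.n_chromosomes:
            raise ValueError(
                f"n_genes ({self.n_genes}) < n_chromosomes "
                f"({self.n_chromosomes}): infeasible layout"
            )
        if self.n_chromosomes < 1 or self.codon_length < 1:
            raise ValueError("n_chromosomes and codon_length must be >= 1")
        for name in ("loss_prob", "loss_bias", "tandem_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        ages = [self.speciation_ages[0], self.speciation_ages[1],
                self.tandem_age]
        if self.wgd_age is not None:
            ages.append(self.wgd_age)
        if any(a < 0 for a in ages):
            raise ValueError("ages must be >= 0")
        if self.syn_rate < 0 or self.ka_ks_ratio < 0:
            raise ValueError("rates must be >= 0")
        if self.wgd_age is not None and self.wgd_age > self.speciation_ages[0]:
            raise ValueError("wgd_age must not predate the outgroup split")


@dataclass
class SimTruth:
    """Ground truth of one simulation run.

    ``wgd_pairs``/``ortholog_pairs``/``tandem_pairs`` are (gene_a, gene_b,
    divergence age in My) triples; ``loss_events`` are (species, ancestral
    gene, subgenome) triples; ``telomere_intervals`` are (species, scaffold,
    start, end) planted arrays (0-based half-open); ``ancestor_of`` maps
    every emitted gene id to its ancestral gene id.
    """

    wgd_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    tandem_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    loss_events: list[tuple[str, str, str]] = field(default_factory=list)
    telomere_intervals: list[tuple[str, str, int, int]] = field(
        default_factory=list
    )
    ancestor_of: dict[str, str] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    # species -> scaffold -> sequence
    chromosomes: dict[str, dict[str, str]]
    # species -> ordered gene models
    genes: dict[str, list[GeneModel]]
    truth: SimTruth

    def cds_dict(self, species: str) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes[species]}


# ---------------------------------------------------------------------------
# sequence evolution


def random_cds(n_codons: int, rng: np.random.Generator,
               fourfold_only: bool = True) -> str:
    if fourfold_only:
        pool = FOURFOLD_CODONS
    else:
        pool = tuple(c for c, aa in CODON_TO_AA.items()
                     if aa != "*" and c != "ATG")
    idx = rng.integers(0, len(pool), size=n_codons)
    return "".join(pool[i] for i in idx)


def _site_is_synonymous(codon: str, pos: int) -> bool:
    """True when every single-base change at pos preserves the amino acid."""
    aa = CODON_TO_AA[codon]
    for b in _BASES:
        if b == codon[pos]:
            continue
        if CODON_TO_AA[codon[:pos] + b + codon[pos + 1 :]] != aa:
            return False
    return True


def evolve_cds(
    cds: str,
    branch_ks: float,
    branch_ka: float,
    rng: np.random.Generator | int,
    fourfold_only: bool = True,
) -> str:
    """Apply a Poisson substitution process to a CDS.

    Synonymous sites receive on average ``branch_ks`` substitutions per
    site, nonsynonymous sites ``branch_ka``; multiple hits at a site are
    allowed (each hit draws a uniform alternative base), so the
    Jukes–Cantor-corrected estimator is consistent. Substitutions that
    would create a stop codon — or, with ``fourfold_only``, leave the
    four-fold-degenerate codon set — are redrawn among the allowed bases.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if branch_ks < 0 or branch_ka < 0:
        raise ValueError("branch lengths must be >= 0")
    if len(cds) % 3 != 0:
        raise InvalidCdsError(f"CDS length {len(cds)} not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise InvalidCdsError("stop codon in input CDS")
    if branch_ks == 0 and branch_ka == 0:
        return cds

    out = []
    for codon in codons:
        cur = codon
        for pos in range(3):
            syn = _site_is_synonymous(codon, pos)
            lam = branch_ks if syn else branch_ka
            if lam == 0:
                continue
            for _ in range(rng.poisson(lam)):
                allowed = []
                for b in _BASES:
                    if b == cur[pos]:
                        continue
                    mut = cur[:pos] + b + cur[pos + 1 :]
                    if mut in STOP_CODONS:
                        continue
                    if fourfold_only and mut not in _FOURFOLD_SET:
                        continue
                    allowed.append(b)
                if not allowed:
                    continue
                b = allowed[int(rng.integers(0, len(allowed)))]
                cur = cur[:pos] + b + cur[pos + 1 :]
        out.append(cur)
    return "".join(out)


# ---------------------------------------------------------------------------
# clade simulation


def _chromosome_of(gene_idx: int, n_genes: int, n_chrom: int) -> int:
    per = -(-n_genes // n_chrom)  # ceil division; contiguous blocks
    return min(gene_idx // per, n_chrom - 1)


def simulate_clade(config: SimConfig) -> SimResult:
    """Simulate the four-species clade; see the module docstring."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # fixed spawn order => determinism
    ss_anc, ss_out1, ss_out2, ss_ing, ss_layout = root.spawn(5)
    rng_anc = np.random.default_rng(ss_anc)
    r = config.syn_rate
    ka_r = config.syn_rate * config.ka_ks_ratio
    t_out, t_in = config.speciation_ages
    ff = config.fourfold_only

    anc = [random_cds(config.codon_length, rng_anc, ff)
           for _ in range(config.n_genes)]
    gene_names = [f"g{i:05d}" for i in range(config.n_genes)]

    truth = SimTruth()
    seqs: dict[str, dict[str, str]] = {}  # species -> gene id -> CDS
    sub_of: dict[str, dict[str, str]] = {}  # species -> gene id -> subgenome

    def branch(seq: str, dt: float, rng: np.random.Generator) -> str:
        return evolve_cds(seq, r * dt, ka_r * dt, rng, ff)

    # outgroups: straight descent from the root
    for sp, ss in (("out1", ss_out1), ("out2", ss_out2)):
        rng = np.random.default_rng(ss)
        seqs[sp] = {}
        sub_of[sp] = {}
        for name, a in zip(gene_names, anc):
            gid = f"{sp}_{name}"
            seqs[sp][gid] = branch(a, t_out, rng)
            sub_of[sp][gid] = "A"
            truth.ancestor_of[gid] = name

    # ingroup lineage
    rng_ing = np.random.default_rng(ss_ing)
    wgd = config.wgd_age
    for sp in INGROUPS:
        seqs[sp] = {}
        sub_of[sp] = {}
    if wgd is not None and wgd >= t_in:
        # shared WGD on the ingroup stem
        for name, a in zip(gene_names, anc):
            pre = branch(a, t_out - wgd, rng_ing)  # root -> WGD
            for sub in ("A", "B"):
                stem = branch(pre, wgd - t_in, rng_ing)  # WGD -> split
                for sp in INGROUPS:
                    gid = f"{sp}_{name}_{sub}"
                    seqs[sp][gid] = branch(stem, t_in, rng_ing)
                    sub_of[sp][gid] = sub
                    truth.ancestor_of[gid] = name
            for sp in INGROUPS:
                truth.wgd_pairs.append(
                    (f"{sp}_{name}_A", f"{sp}_{name}_B", float(wgd))
                )
            for sub in ("A", "B"):
                truth.ortholog_pairs.append(
                    (f"ingA_{name}_{sub}", f"ingB_{name}_{sub}", float(t_in))
                )
    else:
        # no WGD, or lineage-specific WGDs after the ingroup split
        for name, a in zip(gene_names, anc):
            pre = branch(a, t_out - t_in, rng_ing)  # root -> ingroup split
            for sp in INGROUPS:
                if wgd is None:
                    gid = f"{sp}_{name}"
                    seqs[sp][gid] = branch(pre, t_in, rng_ing)
                    sub_of[sp][gid] = "A"
                    truth.ancestor_of[gid] = name
                else:
                    node = branch(pre, t_in - wgd, rng_ing)
                    for sub in ("A", "B"):
                        gid = f"{sp}_{name}_{sub}"
                        seqs[sp][gid] = branch(node, wgd, rng_ing)
                        sub_of[sp][gid] = sub
                        truth.ancestor_of[gid] = name
                    truth.wgd_pairs.append(
                        (f"{sp}_{name}_A", f"{sp}_{name}_B", float(wgd))
                    )
            if wgd is None:
                truth.ortholog_pairs.append(
                    (f"ingA_{name}", f"ingB_{name}", float(t_in))
                )
            else:
                truth.ortholog_pairs.append(
                    (f"ingA_{name}_A", f"ingB_{name}_A", float(t_in))
                )

    # out1 vs ingA orthologs diverge at the root (subgenome A side if WGD)
    for name in gene_names:
        a_id = f"ingA_{name}_A" if (wgd is not None) else f"ingA_{name}"
        truth.ortholog_pairs.append((f"out1_{name}", a_id, float(t_out)))

    # fractionation: per ingroup species, per ancestral gene
    rng_loss = np.random.default_rng(ss_layout.spawn(1)[0])
    if wgd is not None:
        for sp in INGROUPS:
            for name in gene_names:
                if rng_loss.random() < config.loss_prob:
                    sub = "B" if rng_loss.random() < config.loss_bias else "A"
                    gid = f"{sp}_{name}_{sub}"
                    if gid in seqs[sp]:
                        del seqs[sp][gid]
                        del sub_of[sp][gid]
                        truth.loss_events.append((sp, name, sub))

    # tandem duplicates, adjacent insertion handled at layout time
    rng_tand = np.random.default_rng(ss_layout)
    tandems: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES}
    for sp in SPECIES:
        for gid in list(seqs[sp]):
            if rng_tand.random() < config.tandem_prob:
                tid = f"{gid}_t"
                seqs[sp][tid] = evolve_cds(
                    seqs[sp][gid], 2 * r * config.tandem_age,
                    2 * ka_r * config.tandem_age, rng_tand, ff,
                )
                sub_of[sp][tid] = sub_of[sp][gid]
                truth.ancestor_of[tid] = truth.ancestor_of[gid]
                truth.tandem_pairs.append((gid, tid, float(config.tandem_age)))
                tandems[sp][gid] = tid

    # genome layout: collinear with the ancestor; subgenomes on separate
    # chromosome copies (a WGD doubles the chromosome count)
    chromosomes: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneModel]] = {}
    telo = TELOMERE_UNIT * config.telomere_repeats_per_end
    telo_rc = revcomp(telo)
    rng_seq = np.random.default_rng(ss_layout.spawn(2)[1])
    for sp in SPECIES:
        chromosomes[sp] = {}
        genes[sp] = []
        subgenomes = sorted({sub_of[sp][g] for g in seqs[sp]})
        for sub in subgenomes:
            for ci in range(config.n_chromosomes):
                if len(subgenomes) > 1:
                    scaf = f"{sp}_chr{sub}{ci + 1}"
                else:
                    scaf = f"{sp}_chr{ci + 1}"
                parts = [telo]
                pos = len(telo)
                ordered: list[tuple[str, str]] = []
                for gi, name in enumerate(gene_names):
                    if _chromosome_of(gi, config.n_genes,
                                      config.n_chromosomes) != ci:
                        continue
                    for gid in (
                        f"{sp}_{name}_{sub}" if len(subgenomes) > 1
                        else f"{sp}_{name}",
                    ):
                        if gid in seqs[sp]:
                            ordered.append((gid, seqs[sp][gid]))
                            if gid in tandems[sp]:
                                tid = tandems[sp][gid]
                                ordered.append((tid, seqs[sp][tid]))
                for gid, cds in ordered:
                    spacer = "".join(
                        _BASES[i] for i in rng_seq.integers(
                            0, 4, size=config.intergenic_len)
                    )
                    parts.append(spacer)
                    pos += config.intergenic_len
                    strand = "+" if rng_seq.random() < 0.5 else "-"
                    parts.append(cds if strand == "+" else revcomp(cds))
                    genes[sp].append(GeneModel(
                        gene_id=gid, scaffold=scaf, rank=-1,
                        start=pos, end=pos + len(cds), strand=strand,
                        cds=cds,
                    ))
                    pos += len(cds)
                parts.append("".join(
                    _BASES[i] for i in rng_seq.integers(
                        0, 4, size=config.intergenic_len)
                ))
                pos += config.intergenic_len
                parts.append(telo_rc)
                seq = "".join(parts)
                chromosomes[sp][scaf] = seq
                truth.telomere_intervals.append((sp, scaf, 0, len(telo)))
                truth.telomere_intervals.append(
                    (sp, scaf, len(seq) - len(telo_rc), len(seq))
                )
        assign_ranks(genes[sp])
        genes[sp].sort(key=lambda g: (g.scaffold, g.rank))
    return SimResult(config=config, chromosomes=chromosomes, genes=genes,
                     truth=truth)


# ---------------------------------------------------------------------------
# synthetic similarity hits

def kmer_hits(
    cds_a: dict[str, str],
    cds_b: dict[str, str] | None = None,
    k: int = 10,
    min_jaccard: float = 0.03,
) -> list[GeneHit]:
    """All-vs-all k-mer Jaccard similarity as a stand-in for BLAST.

    Only used on synthetic data; real analyses consume externally computed
    12-column tabular hits. Within-genome mode (``cds_b=None``) compares all
    unordered pairs of one gene set.
    """
    def kmers(s: str) -> frozenset[str]:
        return frozenset(s[i : i + k] for i in range(len(s) - k + 1))

    sets_a = {g: kmers(s) for g, s in cds_a.items()}
    if cds_b is None:
        names = sorted(sets_a)
        hits = []
        for i, ga in enumerate(names):
            for gb in names[i + 1 :]:
                inter = len(sets_a[ga] & sets_a[gb])
                if not inter:
                    continue
                j = inter / len(sets_a[ga] | sets_a[gb])
                if j >= min_jaccard:
                    hits.append(GeneHit(ga, gb, score=1000.0 * j,
                                        evalue=10.0 ** (-200 * j)))
        return hits
    sets_b = {g: kmers(s) for g, s in cds_b.items()}
    hits = []
    for ga, sa in sorted(sets_a.items()):
        for gb, sb in sorted(sets_b.items()):
            inter = len(sa & sb)
            if not inter:
                continue
            j = inter / len(sa | sb)
            if j >= min_jaccard:
                hits.append(GeneHit(ga, gb, score=1000.0 * j,
                                    evalue=10.0 ** (-200 * j)))
    return hits


# ---------------------------------------------------------------------------
# writers


def write_genomes(result: SimResult, outdir: str | Path) -> dict[str, dict]:
    """Write per-species chromosome FASTA, CDS FASTA and GFF3 + truth log.

    Returns a manifest of written paths.
    """
    from .io import write_fasta, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for sp in SPECIES:
        d = outdir / sp
        d.mkdir(exist_ok=True)
        chrom_fa = d / f"{sp}.chromosomes.fasta"
        cds_fa = d / f"{sp}.cds.fasta"
        gff = d / f"{sp}.genes.gff3"
        write_fasta(result.chromosomes[sp], chrom_fa)
        write_fasta(result.cds_dict(sp), cds_fa)
        write_gff3(result.genes[sp], gff)
        manifest[sp] = {"chromosomes": str(chrom_fa), "cds": str(cds_fa),
                        "gff3": str(gff)}

    t = result.truth
    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(
            {
                "config": asdict(result.config),
                "wgd_pairs": t.wgd_pairs,
                "ortholog_pairs": t.ortholog_pairs,
                "tandem_pairs": t.tandem_pairs,
                "loss_events": t.loss_events,
                "telomere_intervals": t.telomere_intervals,
                "ancestor_of": t.ancestor_of,
            },
            fh, indent=1,
        )
    truth_tsv = outdir / "truth_pairs.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("kind\tgene_a\tgene_b\tage_my\n")
        for kind, pairs in (("wgd", t.wgd_pairs),
                            ("ortholog", t.ortholog_pairs),
                            ("tandem", t.tandem_pairs)):
            for a, b, age in pairs:
                fh.write(f"{kind}\t{a}\t{b}\t{age}\n")
    manifest["truth"] = {"json": str(truth_json), "tsv": str(truth_tsv)}
    return manifest


def pangene_table(result: SimResult):
    """Per-ancestral-gene copy counts across the four species.

    Returns a DataFrame with one row per ancestral gene (pangene) and one
    copy-count column per species, tandem duplicates included — the same
    shape a syntenic pangene caller would produce on real genomes.
    """
    import pandas as pd

    counts = {sp: {} for sp in SPECIES}
    members = {sp: {} for sp in SPECIES}
    for sp in SPECIES:
        for g in result.genes[sp]:
            anc = result.truth.ancestor_of[g.gene_id]
            counts[sp][anc] = counts[sp].get(anc, 0) + 1
            members[sp].setdefault(anc, []).append(g.gene_id)
    names = sorted({n for sp in SPECIES for n in counts[sp]})
    rows = []
    for n in names:
        row = {"pangene": n}
        for sp in SPECIES:
            row[sp] = counts[sp].get(n, 0)
            row[f"{sp}_genes"] = ",".join(sorted(members[sp].get(n, [])))
        rows.append(row)
    return pd.DataFrame(rows)
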