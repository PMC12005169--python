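"""Pairwise Ka/Ks estimation by the Nei–Gojobori (1986) counting method.

The estimator works on a protein-guided codon alignment of two CDS:

1. fractional synonymous (S) and nonsynonymous (N) site counts per codon,
   averaged between the two sequences, with S + N = 3 x compared columns;
2. observed synonymous (Sd) and nonsynonymous (Nd) differences, where codons
   differing at several positions are resolved by averaging over all minimal
   single-substitution pathways, excluding pathways that pass through a stop
   codon;
3. proportions ps = Sd/S and pn = Nd/N corrected for multiple hits with the
   Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3), undefined (``saturated``)
   when p >= 3/4.

Mutations that would create a stop codon are counted as nonsynonymous during
site counting, which keeps the S + N invariant exact; a codon column whose
every substitution pathway crosses a stop is dropped from both site and
difference counts. Gap columns and columns containing non-ACGT bases are
excluded pairwise. The universal nuclear genetic code is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"
GAP_CODON = "---"


class InvalidCdsError(ValueError):
    """Raised when a CDS cannot be interpreted as a run of sense codons."""


def _codons(cds: str, name: str = "cds") -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise InvalidCdsError(f"{name}: length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise InvalidCdsError(f"{name}: internal stop codon {c} at codon {i}")
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]  # trailing stop is not part of the protein
    return codons


def translate_codons(codons: list[str]) -> str:
    return "".join(CODON_TO_AA.get(c, "X") for c in codons)


@dataclass
class CodonAlignment:
    """Column-paired codons for two CDS; gaps only as whole triplets."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon column counts differ between sequences")

    def __len__(self) -> int:
        return len(self.codons_a)

    @property
    def complete_columns(self) -> list[tuple[str, str]]:
        """Columns with a real codon on both sides, ACGT only."""
        out = []
        for ca, cb in zip(self.codons_a, self.codons_b):
            if ca == GAP_CODON or cb == GAP_CODON:
                continue
            if any(b not in _BASES for b in ca + cb):
                continue
            out.append((ca, cb))
        return out


def align_codon_pair(
    cds_a: str,
    cds_b: str,
    matrix: str = "BLOSUM62",
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
) -> CodonAlignment:
    """Globally align two CDS in protein space and back-translate to codons.

    Gaps therefore always land on codon boundaries. Among co-optimal
    alignments the aligner's first (deterministic) traceback is used.
    """
    codons_a = _codons(cds_a, "cds_a")
    codons_b = _codons(cds_b, "cds_b")
    if not codons_a or not codons_b:
        raise InvalidCdsError("empty CDS")
    prot_a = translate_codons(codons_a)
    prot_b = translate_codons(codons_b)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(prot_a, prot_b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])

    cols_a: list[str] = []
    cols_b: list[str] = []
    ia = ib = 0
    for ra, rb in zip(aligned_a, aligned_b):
        if ra == "-":
            cols_a.append(GAP_CODON)
        else:
            cols_a.append(codons_a[ia])
            ia += 1
        if rb == "-":
            cols_b.append(GAP_CODON)
        else:
            cols_b.append(codons_b[ib])
            ib += 1
    return CodonAlignment(cols_a, cols_b)


@dataclass
class KsEstimate:
    """NG86 estimate for one gene pair; ``ks``/``ka`` are NaN when saturated."""

    ka: float
    ks: float
    S: float
    N: float
    Sd: float
    Nd: float
    saturated: bool
    columns: int = 0


def _syn_site_fraction(codon: str) -> float:
    """Fractional synonymous site count of one codon (0..3).

    Each position contributes (# synonymous single-base changes)/3; a change
    to a stop codon counts as nonsynonymous, so per-codon s + n = 3 exactly.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TO_AA[mut] == aa:
                s += 1.0 / 3.0
    return s


def _pathway_differences(ca: str, cb: str) -> tuple[float, float] | None:
    """Average (syn, nonsyn) step counts over minimal substitution pathways.

    Pathways through stop codons are excluded; returns None when every
    pathway is blocked (the column is then dropped entirely).
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_valid = 0
    for order in itertools.permutations(diff_pos):
        cur = ca
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_valid += 1
    if n_valid == 0:
        return None
    return syn_tot / n_valid, nsyn_tot / n_valid


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; domain p < 3/4."""
    if p >= 0.75:
        return math.nan
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(aln: CodonAlignment) -> KsEstimate:
    """Nei–Gojobori (1986) Ka/Ks from a codon alignment.

    Raises ``ValueError`` when no comparable codon column remains; saturation
    (ps or pn >= 3/4) is flagged on the result, not raised.
    """
    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in aln.complete_columns:
        diffs = _pathway_differences(ca, cb)
        if diffs is None:
            continue
        sa = _syn_site_fraction(ca)
        sb = _syn_site_fraction(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
        used += 1
    if used == 0:
        raise ValueError("no comparable (non-gap, ACGT) codon columns")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = math.isnan(ks) or math.isnan(ka)
    return KsEstimate(ka=ka, ks=ks, S=S, N=N, Sd=Sd, Nd=Nd,
                      saturated=saturated, columns=used)


def ka_ks_pair(cds_a: str, cds_b: str, **align_kwargs) -> KsEstimate:
    """Convenience: align two CDS and run NG86."""
    return ng86(align_codon_pair(cds_a, cds_b, **align_kwargs))


def ka_ks_batch(
    pairs: list[tuple[str, str]],
    cds: dict[str, str],
    **align_kwargs,
):
    """NG86 over a list of (gene_a, gene_b) id pairs.

    Returns a pandas DataFrame with the batch-output column set
    (gene_a, gene_b, ka, ks, S, N, Sd, Nd, saturated). Pairs whose CDS is
    missing or invalid are skipped with a NaN row rather than aborting the
    batch.
    """
    import pandas as pd

    rows = []
    for a, b in pairs:
        try:
            est = ka_ks_pair(cds[a], cds[b], **align_kwargs)
            rows.append((a, b, est.ka, est.ks, est.S, est.N, est.Sd, est.Nd,
                         est.saturated))
        except (KeyError, InvalidCdsError, ValueError):
            rows.append((a, b, math.nan, math.nan, math.nan, math.nan,
                         math.nan, math.nan, True))
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "ka", "ks", "S", "N", "Sd", "Nd",
                 "saturated"],
    )
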