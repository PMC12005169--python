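"""Post-WGD gene retention, fractionation profiles and GO enrichment.

Three analyses of what happens to duplicated genes after a whole-genome
duplication:

* **Fractionation profiles** — against an unduplicated reference genome,
  for each window of 100 consecutive reference genes, the percentage of
  genes retained on each of the two most homologous scaffolds of the
  duplicated genome (the homoeologs). Parallel retention curves mean
  unbiased fractionation; separated curves are the signature of a dominant
  subgenome (allopolyploidy). A two-sided exact sign test on the per-window
  retention differences makes the visual comparison formal.

* **Retention classes** — pangenes (syntenic ortholog groups with a copy
  count per species) across two non-WGD outgroups and two WGD-bearing
  ingroups are filtered to those single-copy in both outgroups with each
  ingroup at 1 or 2 copies, then partitioned into: duplicates retained in
  both ingroups, reverted to single copy in both, or retained in only one.

* **GO over-representation** — one-sided Fisher exact (hypergeometric)
  test per GO term of a gene group against a universe, with the expected
  count reported; p-values are deliberately left uncorrected for multiple
  testing, as is conventional for exploratory GO scans.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class RetentionClass(enum.Enum):
    RETAINED_BOTH = "retained_both"
    SINGLE_BOTH = "single_both"
    RETAINED_A_ONLY = "retained_A_only"
    RETAINED_B_ONLY = "retained_B_only"
    FILTERED_OUT = "filtered_out"


@dataclass
class PangeneRow:
    pangene: str
    out1: int
    out2: int
    ingroup_a: int
    ingroup_b: int

    def __post_init__(self) -> None:
        for v in (self.out1, self.out2, self.ingroup_a, self.ingroup_b):
            if v < 0:
                raise ValueError(f"pangene {self.pangene}: negative copy count")


def classify_pangene(row: PangeneRow) -> RetentionClass:
    """Retention class of one pangene (see module docstring for the rule)."""
    if row.out1 != 1 or row.out2 != 1:
        return RetentionClass.FILTERED_OUT
    a, b = row.ingroup_a, row.ingroup_b
    if a not in (1, 2) or b not in (1, 2):
        return RetentionClass.FILTERED_OUT
    if a == 2 and b == 2:
        return RetentionClass.RETAINED_BOTH
    if a == 1 and b == 1:
        return RetentionClass.SINGLE_BOTH
    if a == 2:
        return RetentionClass.RETAINED_A_ONLY
    return RetentionClass.RETAINED_B_ONLY


def classify_retention(
    rows: list[PangeneRow],
) -> tuple[list[RetentionClass], dict[str, int]]:
    """Classify every pangene; returns per-row classes and class totals.

    The totals are a partition: they sum exactly to the number of rows.
    """
    classes = [classify_pangene(r) for r in rows]
    totals = {c.value: 0 for c in RetentionClass}
    for c in classes:
        totals[c.value] += 1
    return classes, totals


@dataclass
class FractionationWindow:
    ref_scaffold: str
    index: int
    n_genes: int
    homoeolog_1: str
    homoeolog_2: str
    retention_1: float  # percent of window genes present on homoeolog 1
    retention_2: float
    truncated: bool = False


def fractionation_profile(
    ref_genes: list[tuple[str, str]],
    ortholog_map: dict[str, list[str]],
    window: int = 100,
    step: int | None = None,
) -> list[FractionationWindow]:
    """Windowed retention on the two most homologous scaffolds.

    ``ref_genes`` is the ordered reference gene list as (gene_id, scaffold);
    ``ortholog_map`` gives, per reference gene, the duplicated-genome
    scaffolds carrying a syntenic copy. Per reference scaffold the two
    target scaffolds with most mapped genes are taken as the homoeologs
    (ties broken by scaffold name); windows are consecutive
    non-overlapping blocks of ``window`` genes unless a ``step`` makes
    them slide. A final shorter window is emitted flagged as truncated.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    step = step or window
    by_scaffold: dict[str, list[str]] = {}
    for gid, scaf in ref_genes:
        by_scaffold.setdefault(scaf, []).append(gid)

    out: list[FractionationWindow] = []
    for scaf in sorted(by_scaffold):
        genes = by_scaffold[scaf]
        counts: dict[str, int] = {}
        for gid in genes:
            for tgt in ortholog_map.get(gid, ()):  # scaffold may repeat
                counts[tgt] = counts.get(tgt, 0) + 1
        top = sorted(counts, key=lambda s: (-counts[s], s))[:2]
        while len(top) < 2:
            top.append("")
        h1, h2 = top
        idx = 0
        for start in range(0, len(genes), step):
            chunk = genes[start : start + window]
            if not chunk:
                break
            r1 = sum(1 for g in chunk if h1 and h1 in ortholog_map.get(g, ()))
            r2 = sum(1 for g in chunk if h2 and h2 in ortholog_map.get(g, ()))
            out.append(FractionationWindow(
                ref_scaffold=scaf, index=idx, n_genes=len(chunk),
                homoeolog_1=h1, homoeolog_2=h2,
                retention_1=100.0 * r1 / len(chunk),
                retention_2=100.0 * r2 / len(chunk),
                truncated=len(chunk) < window,
            ))
            idx += 1
            if start + window >= len(genes):
                break
    return out


def fractionation_bias_test(
    windows: list[FractionationWindow],
    min_windows: int = 5,
) -> tuple[float, float, float]:
    """Two-sided exact sign test for subgenome-biased fractionation.

    Per-window retention differences (homoeolog 1 minus homoeolog 2) are
    reduced to their signs, zeros dropped, and tested against a fair coin.
    Returns (p_value, mean retention 1, mean retention 2); all-zero
    differences give p = 1.
    """
    if len(windows) < min_windows:
        raise ValueError(f"need at least {min_windows} windows")
    d = [w.retention_1 - w.retention_2 for w in windows]
    mean1 = float(np.mean([w.retention_1 for w in windows]))
    mean2 = float(np.mean([w.retention_2 for w in windows]))
    pos = sum(1 for x in d if x > 0)
    neg = sum(1 for x in d if x < 0)
    if pos + neg == 0:
        return 1.0, mean1, mean2
    p = stats.binomtest(pos, pos + neg, 0.5, alternative="two-sided").pvalue
    return float(p), mean1, mean2


@dataclass
class EnrichmentRow:
    go_id: str
    term: str
    total: int  # genes annotated with the term in the universe
    count: int  # genes annotated with the term in the group
    expected: float
    p_value: float


def go_enrichment(
    group: set[str],
    universe: set[str],
    gene_to_go: dict[str, set[str]],
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided Fisher exact GO over-representation scan.

    For each GO term annotated to at least one universe gene, tests whether
    the group contains more term genes than a hypergeometric draw of
    ``len(group)`` genes from the universe would. P-values are reported
    raw (uncorrected). Rows are sorted by p-value, then GO id.
    """
    if not group:
        raise ValueError("empty gene group")
    extra = group - universe
    if extra:
        raise ValueError(f"group genes outside the universe: {sorted(extra)[:3]}")
    term_names = term_names or {}
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for go in gene_to_go.get(gene, ()):  # unannotated genes allowed
            term_genes.setdefault(go, set()).add(gene)
    if not term_genes:
        raise ValueError("gene->GO map covers no universe gene")
    M, n_draw = len(universe), len(group)
    rows = []
    for go in sorted(term_genes):
        genes = term_genes[go]
        total = len(genes)
        count = len(genes & group)
        expected = total * n_draw / M
        # P(X >= count) for X ~ Hypergeom(M, total, n_draw)
        p = float(stats.hypergeom.sf(count - 1, M, total, n_draw))
        rows.append(EnrichmentRow(
            go_id=go, term=term_names.get(go, ""), total=total, count=count,
            expected=expected, p_value=min(p, 1.0),
        ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values(["p_value", "go_id"]).reset_index(drop=True)
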