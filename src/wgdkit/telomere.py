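"""Telomere repeat window scan and contig-end classification.

The scan counts occurrences of a tandem-repeat query — by default three
units of the canonical plant telomere repeat TTTAGGG, i.e. the 21-bp
sequence TTTAGGGTTTAGGGTTTAGGG — and of its reverse complement in
non-overlapping 1 Mb windows along each scaffold, and retains windows with
at least 20 copies. A scaffold whose first and last windows are both
retained carries telomeres at both ends (telomere-to-telomere); one end or
neither give the other two classes.

Occurrences are counted at every matching start position (overlapping
matches count), so a perfect array of k repeat units contains exactly
k - 2 copies of the 3-unit query. A match is assigned to the window
containing its start, which lets a match span a window boundary without
being lost or double-counted. N bases never match.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class TelomereScanConfig:
    motif: str = "TTTAGGG"
    repeats: int = 3  # query = motif * repeats (21 bp by default)
    window: int = 1_000_000
    min_count: int = 20
    joint: bool = True  # threshold applies to forward + reverse jointly

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError("motif must be a non-empty A/C/G/T string")
        if self.repeats < 1 or self.min_count < 1:
            raise ValueError("repeats and min_count must be >= 1")
        if self.window < len(self.motif) * self.repeats:
            raise ValueError("window shorter than the query sequence")

    @property
    def query(self) -> str:
        return self.motif * self.repeats


@dataclass
class TelomereWindow:
    scaffold: str
    index: int
    start: int  # 0-based half-open
    end: int
    fwd_count: int
    rev_count: int
    retained: bool


@dataclass
class ContigTelomereStatus:
    scaffold: str
    classification: str  # both_ends | one_end | none
    five_prime: bool
    three_prime: bool


def count_overlapping(seq: str, query: str) -> int:
    """Occurrences of ``query`` in ``seq`` counting every start position."""
    n = 0
    i = seq.find(query)
    while i != -1:
        n += 1
        i = seq.find(query, i + 1)
    return n


def scan_windows(
    scaffold: str,
    sequence: str,
    config: TelomereScanConfig | None = None,
) -> list[TelomereWindow]:
    """Tile one scaffold into windows and count query occurrences in each."""
    config = config or TelomereScanConfig()
    seq = sequence.upper()
    if not seq:
        return []
    q_fwd = config.query
    q_rev = _revcomp(q_fwd)
    qlen = len(q_fwd)
    out = []
    idx = 0
    for start in range(0, len(seq), config.window):
        end = min(start + config.window, len(seq))
        # search region extends past the window end so a match starting
        # inside the window but crossing the boundary is still seen; the
        # count filter below keeps only starts inside [start, end)
        region = seq[start : end + qlen - 1]
        fwd = _count_starts_in(region, q_fwd, end - start)
        rev = _count_starts_in(region, q_rev, end - start)
        if config.joint:
            retained = fwd + rev >= config.min_count
        else:
            retained = fwd >= config.min_count or rev >= config.min_count
        out.append(TelomereWindow(
            scaffold=scaffold, index=idx, start=start, end=end,
            fwd_count=fwd, rev_count=rev, retained=retained,
        ))
        idx += 1
    return out


def _count_starts_in(region: str, query: str, limit: int) -> int:
    """Count matches of query in region whose start is < limit."""
    n = 0
    i = region.find(query)
    while i != -1 and i < limit:
        n += 1
        i = region.find(query, i + 1)
    return n


def classify_contig(windows: list[TelomereWindow]) -> ContigTelomereStatus:
    """Classify a scaffold by retained telomeric windows at its two ends."""
    if not windows:
        raise ValueError("no windows for scaffold")
    scaffold = windows[0].scaffold
    if any(w.scaffold != scaffold for w in windows):
        raise ValueError("windows from more than one scaffold")
    ordered = sorted(windows, key=lambda w: w.index)
    five = ordered[0].retained
    three = ordered[-1].retained
    if five and three:
        cls = "both_ends"
    elif five or three:
        cls = "one_end"
    else:
        cls = "none"
    return ContigTelomereStatus(scaffold=scaffold, classification=cls,
                                five_prime=five, three_prime=three)


def scan_genome(
    chromosomes: dict[str, str],
    config: TelomereScanConfig | None = None,
) -> tuple[list[TelomereWindow], list[ContigTelomereStatus]]:
    """Scan every scaffold of a genome; returns windows and per-contig status."""
    config = config or TelomereScanConfig()
    windows: list[TelomereWindow] = []
    statuses: list[ContigTelomereStatus] = []
    for scaf in sorted(chromosomes):
        w = scan_windows(scaf, chromosomes[scaf], config)
        windows.extend(w)
        if w:
            statuses.append(classify_contig(w))
    return windows, statuses
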