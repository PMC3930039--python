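"""Alignment-level diversity statistics and fixed-difference SNP discovery.

Works on a gapped multiple alignment of cDNA sequences carrying a pheromone-race
label (E or Z) per record.  Provides p-distances, nucleotide diversity (pi),
segregating-site counts, Tajima's D, a sliding-window divergence scan, and
detection of SNPs fixed differentially between the two races.

Coordinates are 1-based inclusive alignment columns throughout.  Positions in
the ungapped consensus (the coordinate system in which diagnostic SNPs such as
857/995/1005 are reported) are reached through :meth:`AlignedPanel.column_to_consensus`
and :meth:`AlignedPanel.consensus_to_column`.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

VALID_ALPHABET = set("ACGTN-")
BASES = set("ACGT")

__all__ = [
    "AlignedPanel",
    "WindowStat",
    "SNPSite",
    "mean_pairwise_distance",
    "nucleotide_diversity_pi",
    "segregating_sites",
    "tajimas_d",
    "sliding_window_scan",
    "merge_flagged_regions",
    "fixed_differences",
]


@dataclass(frozen=True)
class PanelRecord:
    id: str
    group: str  # "E", "Z" or "unlabeled"
    sequence: str


@dataclass
class AlignedPanel:
    """A gapped, group-labeled DNA sequence matrix with column coordinates."""

    records: list[PanelRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty panel")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        for r in self.records:
            bad = set(r.sequence.upper()) - VALID_ALPHABET
            if bad:
                raise ValueError(f"record {r.id}: invalid characters {sorted(bad)}")
            if r.group not in ("E", "Z", "unlabeled"):
                raise ValueError(f"record {r.id}: unknown group {r.group!r}")
        # normalise case once
        self.records = [
            PanelRecord(r.id, r.group, r.sequence.upper()) for r in self.records
        ]

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def n(self) -> int:
        return len(self.records)

    def groups(self) -> dict[str, list[PanelRecord]]:
        out: dict[str, list[PanelRecord]] = {}
        for r in self.records:
            out.setdefault(r.group, []).append(r)
        return out

    def subset(self, group: str | None = None) -> "AlignedPanel":
        """Panel restricted to one group label; ``None`` keeps everything."""
        if group is None:
            return self
        recs = [r for r in self.records if r.group == group]
        if not recs:
            raise ValueError(f"no records with group {group!r}")
        return AlignedPanel(recs)

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-byte characters."""
        return np.array([list(r.sequence) for r in self.records], dtype="U1")

    def column(self, col: int) -> list[str]:
        """Bases at a 1-based column."""
        self._check_column(col)
        return [r.sequence[col - 1] for r in self.records]

    def _check_column(self, col: int) -> None:
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")

    # --- consensus coordinate mapping -------------------------------------
    def consensus(self) -> str:
        """Majority-rule consensus across rows, including gap characters.

        A column whose majority character is a gap maps to no consensus
        position; ties are broken toward bases, then alphabetically.
        """
        cols = []
        for i in range(self.length):
            counts = Counter(r.sequence[i] for r in self.records)
            # favour real bases over '-'/'N' on ties
            best = max(
                counts.items(), key=lambda kv: (kv[1], kv[0] in BASES, -ord(kv[0][0]))
            )[0]
            cols.append(best)
        return "".join(cols)

    def _consensus_map(self) -> tuple[dict[int, int], dict[int, int]]:
        col2cons: dict[int, int] = {}
        cons2col: dict[int, int] = {}
        pos = 0
        for i, ch in enumerate(self.consensus(), start=1):
            if ch != "-":
                pos += 1
                col2cons[i] = pos
                cons2col[pos] = i
        return col2cons, cons2col

    def column_to_consensus(self, col: int) -> int | None:
        """Ungapped-consensus position of an alignment column (None at gap columns)."""
        self._check_column(col)
        return self._consensus_map()[0].get(col)

    def consensus_to_column(self, pos: int) -> int:
        cons2col = self._consensus_map()[1]
        if pos not in cons2col:
            raise IndexError(f"consensus position {pos} outside 1..{len(cons2col)}")
        return cons2col[pos]

    # --- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(
        cls, fasta: str | Path, groups: str | Path | dict[str, str] | None = None
    ) -> "AlignedPanel":
        """Read an aligned multi-FASTA.

        Group labels come from (in order of precedence) an explicit mapping or
        two-column CSV ``id,group``, else a ``group=E|Z`` token in the FASTA
        header; records with neither are ``unlabeled``.
        """
        mapping: dict[str, str] = {}
        if isinstance(groups, dict):
            mapping = dict(groups)
        elif groups is not None:
            with open(groups, newline="") as fh:
                for row in csv.reader(fh):
                    if not row or row[0].lower() in ("id", "#id"):
                        continue
                    mapping[row[0].strip()] = row[1].strip()
        records = []
        for rec in SeqIO.parse(str(fasta), "fasta"):
            group = mapping.get(rec.id)
            if group is None:
                for token in rec.description.split():
                    if token.startswith("group="):
                        group = token.split("=", 1)[1]
            records.append(PanelRecord(rec.id, group or "unlabeled", str(rec.seq)))
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id} group={r.group}\n{r.sequence}\n")


@dataclass(frozen=True)
class WindowStat:
    start: int
    end: int
    S: int
    pi: float
    tajimas_d: float | None
    flagged: bool
    truncated: bool = False


@dataclass(frozen=True)
class SNPSite:
    """A column fixed for different bases in the E- and Z-labeled groups."""

    column: int
    consensus_position: int | None
    allele_e: str
    allele_z: str
    codon_position: int | str  # 1, 2, 3 or "noncoding"
    synonymous: bool | None


def _resolve_range(panel: AlignedPanel, columns: tuple[int, int] | None) -> tuple[int, int]:
    if columns is None:
        return 1, panel.length
    start, end = columns
    if start < 1 or end > panel.length or end < start:
        raise ValueError(f"invalid column range {start}..{end} for length {panel.length}")
    return start, end


def _pairwise_counts(a: str, b: str, start: int, end: int) -> tuple[int, int]:
    """(mismatches, compared sites) between two rows, pairwise deletion."""
    diff = comp = 0
    for x, y in zip(a[start - 1 : end], b[start - 1 : end]):
        if x in BASES and y in BASES:
            comp += 1
            if x != y:
                diff += 1
    return diff, comp


def mean_pairwise_distance(
    panel: AlignedPanel,
    group: str | None = None,
    between: tuple[str, str] | None = None,
    columns: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Mean p-distance (substitutions per site) with its analytical SE.

    ``group`` restricts to within-group pairs; ``between=("E","Z")`` averages
    only inter-group pairs.  Gapped or ambiguous positions are dropped per pair
    (pairwise deletion).  The standard error is the square root of the mean of
    the per-pair binomial variances p(1-p)/L.
    """
    start, end = _resolve_range(panel, columns)
    if between is not None:
        left = panel.subset(between[0]).records
        right = panel.subset(between[1]).records
        pairs = [(a, b) for a in left for b in right]
    else:
        recs = panel.subset(group).records
        if len(recs) < 2:
            raise ValueError("insufficient sequences")
        pairs = [(recs[i], recs[j]) for i in range(len(recs)) for j in range(i + 1, len(recs))]
    if not pairs:
        raise ValueError("insufficient sequences")
    ps, vs = [], []
    for a, b in pairs:
        diff, comp = _pairwise_counts(a.sequence, b.sequence, start, end)
        if comp == 0:
            raise ValueError(f"no comparable sites between {a.id} and {b.id}")
        p = diff / comp
        ps.append(p)
        vs.append(p * (1 - p) / comp)
    return float(np.mean(ps)), float(math.sqrt(np.mean(vs)))


def nucleotide_diversity_pi(
    panel: AlignedPanel,
    columns: tuple[int, int] | None = None,
    group: str | None = None,
) -> float:
    """Nucleotide diversity pi: mean pairwise differences per site."""
    start, end = _resolve_range(panel, columns)
    if end < start:
        raise ValueError("empty column range")
    d, _ = mean_pairwise_distance(panel, group=group, columns=(start, end))
    return d


def _mean_pairwise_difference_count(panel: AlignedPanel, start: int, end: int) -> float:
    """Mean number of differing sites per pair (not per site), pairwise deletion."""
    recs = panel.records
    total = 0.0
    npairs = 0
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            diff, _ = _pairwise_counts(recs[i].sequence, recs[j].sequence, start, end)
            total += diff
            npairs += 1
    if npairs == 0:
        raise ValueError("insufficient sequences")
    return total / npairs


def segregating_sites(
    panel: AlignedPanel, columns: tuple[int, int] | None = None
) -> int:
    """Count of columns with >= 2 distinct unambiguous bases among rows."""
    start, end = _resolve_range(panel, columns)
    S = 0
    for col in range(start, end + 1):
        bases = {b for b in panel.column(col) if b in BASES}
        if len(bases) >= 2:
            S += 1
    return S


def tajimas_d(
    panel: AlignedPanel, columns: tuple[int, int] | None = None
) -> float | None:
    """Tajima's D over a column range; ``None`` when no sites segregate.

    D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1)) with k the mean pairwise
    difference count and e1, e2 the usual coefficients from the sample size.
    """
    if panel.n < 2:
        raise ValueError("insufficient sequences")
    start, end = _resolve_range(panel, columns)
    S = segregating_sites(panel, (start, end))
    if S == 0:
        return None
    n = panel.n
    k = _mean_pairwise_difference_count(panel, start, end)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (k - S / a1) / math.sqrt(var)


def sliding_window_scan(
    panel: AlignedPanel,
    width: int = 100,
    step: int = 25,
    threshold: float = 2.0,
    columns: tuple[int, int] | None = None,
) -> list[WindowStat]:
    """Tajima's-D scan in overlapping windows (defaults 100 bp / 25-bp steps).

    Windows start at 1, 1+step, ...; the terminal window is truncated at the
    alignment end and marked.  A window is flagged when D is defined and
    exceeds ``threshold``.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    lo, hi = _resolve_range(panel, columns)
    if width > hi - lo + 1:
        raise ValueError("window wider than scanned range")
    out: list[WindowStat] = []
    start = lo
    while start <= hi:
        end = min(start + width - 1, hi)
        truncated = end - start + 1 < width
        d = tajimas_d(panel, (start, end))
        pi = 0.0
        if panel.n >= 2:
            pi = nucleotide_diversity_pi(panel, (start, end))
        S = segregating_sites(panel, (start, end))
        flagged = d is not None and d > threshold
        out.append(WindowStat(start, end, S, pi, d, flagged, truncated))
        if end == hi:
            break
        start += step
    return out


def merge_flagged_regions(windows: Iterable[WindowStat]) -> list[tuple[int, int]]:
    """Merge flagged windows that overlap or touch into divergent regions."""
    flagged = sorted((w.start, w.end) for w in windows if w.flagged)
    regions: list[list[int]] = []
    for s, e in flagged:
        if regions and s <= regions[-1][1] + 1:
            regions[-1][1] = max(regions[-1][1], e)
        else:
            regions.append([s, e])
    return [(s, e) for s, e in regions]


def regions_to_bed(regions: Iterable[tuple[int, int]], name: str = "panel") -> str:
    """Flagged regions as BED lines (explicit 1-based->0-based half-open)."""
    return "".join(f"{name}\t{s - 1}\t{e}\n" for s, e in regions)


def _codon_annotation(
    panel: AlignedPanel, col: int, allele_a: str, allele_b: str, cds_columns: tuple[int, int] | None
) -> tuple[int | str, bool | None]:
    """Codon position and synonymy of a substitution against the consensus frame."""
    if cds_columns is None or not cds_columns[0] <= col <= cds_columns[1]:
        return "noncoding", None
    cds_start, cds_end = cds_columns
    consensus = panel.consensus()[cds_start - 1 : cds_end]
    offset = col - cds_start
    codon_pos = offset % 3 + 1
    codon_start = offset - (codon_pos - 1)
    codon = list(consensus[codon_start : codon_start + 3])
    if len(codon) < 3 or "-" in codon or "N" in codon:
        return codon_pos, None
    alt_a, alt_b = codon.copy(), codon.copy()
    alt_a[codon_pos - 1] = allele_a
    alt_b[codon_pos - 1] = allele_b
    aa_a = str(Seq("".join(alt_a)).translate())
    aa_b = str(Seq("".join(alt_b)).translate())
    return codon_pos, aa_a == aa_b


def fixed_differences(
    panel: AlignedPanel, cds_columns: tuple[int, int] | None = None
) -> list[SNPSite]:
    """Columns fixed for one base in every E sequence and a different base in every Z.

    Columns where any labeled sequence carries a gap or N are excluded.
    ``cds_columns`` (alignment coordinates of the reading frame) enables codon
    position and synonymy annotation.
    """
    groups = panel.groups()
    if "E" not in groups or "Z" not in groups:
        raise ValueError("panel must contain both E- and Z-labeled sequences")
    sites: list[SNPSite] = []
    for col in range(1, panel.length + 1):
        e_bases = {r.sequence[col - 1] for r in groups["E"]}
        z_bases = {r.sequence[col - 1] for r in groups["Z"]}
        if len(e_bases) != 1 or len(z_bases) != 1:
            continue
        (e_base,) = e_bases
        (z_base,) = z_bases
        if e_base not in BASES or z_base not in BASES or e_base == z_base:
            continue
        codon_pos, syn = _codon_annotation(panel, col, e_base, z_base, cds_columns)
        sites.append(
            SNPSite(
                column=col,
                consensus_position=panel.column_to_consensus(col),
                allele_e=e_base,
                allele_z=z_base,
                codon_position=codon_pos,
                synonymous=syn,
            )
        )
    return sites


def windows_to_rows(windows: Sequence[WindowStat]) -> list[dict]:
    """Window statistics as plain dicts for CSV/DataFrame export."""
    return [
        {
            "start": w.start,
            "end": w.end,
            "S": w.S,
            "pi": round(w.pi, 6),
            "tajimas_d": None if w.tajimas_d is None else round(w.tajimas_d, 6),
            "flagged": w.flagged,
            "truncated": w.truncated,
        }
        for w in windows
    ]
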