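"""CAPS (PCR-RFLP) marker design from fixed inter-race SNPs.

A CAPS marker assays a SNP whose one allele completes a restriction enzyme's
recognition site while the other destroys it.  This module scans for such
diagnostic sites, runs in-silico PCR with (possibly degenerate) primers,
digests amplicons, and packages per-allele predicted fragment patterns into
markers that the genotyping module can score against observed gel patterns.

Primer matching is exact under IUPAC degeneracy (no mismatches, no
thermodynamics): the markers being modelled use validated primers.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .diversity import AlignedPanel, SNPSite, BASES

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

__all__ = [
    "Enzyme", "PrimerPair", "Amplicon", "FragmentPattern", "CAPSMarker",
    "DEFAULT_ENZYMES", "iupac_match", "find_sites", "insilico_pcr", "digest",
    "diagnostic_caps_sites", "build_marker", "load_enzymes", "load_primers",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease: recognition sequence + top-strand cut offset.

    ``cut_offset`` is the number of recognition-site bases 5' of the cut on the
    top strand, e.g. TaqI T^CGA has offset 1, NdeII ^GATC has offset 0.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4:
            raise ValueError(f"{self.name}: recognition shorter than 4")
        if any(ch not in IUPAC for ch in rec):
            raise ValueError(f"{self.name}: non-IUPAC recognition {rec!r}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"{self.name}: cut offset outside recognition")
        object.__setattr__(self, "recognition", rec)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == str(Seq(self.recognition).reverse_complement())


# The three enzymes used for the pgfar race assays.
DEFAULT_ENZYMES: dict[str, Enzyme] = {
    "TaqI": Enzyme("TaqI", "TCGA", 1),
    "NdeII": Enzyme("NdeII", "GATC", 0),
    "MseI": Enzyme("MseI", "TTAA", 1),
}


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3' (reverse on the antisense strand)."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for which, seq in (("forward", self.forward), ("reverse", self.reverse)):
            clean = seq.replace(" ", "").upper()
            if len(clean) < 15:
                raise ValueError(f"{self.name} {which} primer shorter than 15 nt")
            if any(ch not in IUPAC for ch in clean):
                raise ValueError(f"{self.name} {which} primer has non-IUPAC characters")
            object.__setattr__(self, which, clean)


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    template_id: str
    start: int  # 1-based inclusive template coordinates, primers included
    end: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("amplicon length inconsistent with coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentPattern:
    """Restriction fragment lengths in descending order."""

    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.fragment_lengths:
            raise ValueError("empty fragment pattern")
        object.__setattr__(
            self, "fragment_lengths", tuple(sorted(self.fragment_lengths, reverse=True))
        )

    @property
    def total(self) -> int:
        return sum(self.fragment_lengths)

    def visible(self, min_len: int = 20) -> "FragmentPattern":
        """Fragments resolvable on a gel (drops pieces below ``min_len``)."""
        kept = tuple(x for x in self.fragment_lengths if x >= min_len)
        return FragmentPattern(kept if kept else (max(self.fragment_lengths),))

    def __str__(self) -> str:
        return "+".join(str(x) for x in self.fragment_lengths)


def iupac_match(pattern: str, text: str) -> bool:
    """Exact match of an IUPAC-degenerate pattern against concrete bases."""
    if len(pattern) != len(text):
        return False
    return all(t in IUPAC.get(p, "") for p, t in zip(pattern, text))


def _scan(pattern: str, sequence: str) -> list[int]:
    """1-based start positions of IUPAC pattern occurrences."""
    L, k = len(sequence), len(pattern)
    return [i + 1 for i in range(L - k + 1) if iupac_match(pattern, sequence[i : i + k])]


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut positions (cut falls after the returned 1-based position).

    Palindromic recognition sequences need only a top-strand scan; a
    non-palindromic enzyme is additionally scanned on the bottom strand, its
    cut reported in top-strand coordinates.
    """
    seq = sequence.upper()
    if "-" in seq:
        raise ValueError("sequence must be gap-free")
    cuts = [pos + enzyme.cut_offset - 1 for pos in _scan(enzyme.recognition, seq)]
    if not enzyme.is_palindromic:
        rc = str(Seq(enzyme.recognition).reverse_complement())
        k = len(rc)
        for pos in _scan(rc, seq):
            # bottom-strand site: top-strand cut mirrors the offset
            cuts.append(pos + (k - enzyme.cut_offset) - 1)
    return sorted(set(c for c in cuts if 0 < c < len(seq)))


def insilico_pcr(template: str, primers: PrimerPair, max_products: int = 1) -> Amplicon:
    """Unique PCR product for a primer pair on a gap-free template.

    The forward primer must match the sense strand and the reverse primer the
    antisense strand (i.e. its reverse complement matches the sense strand),
    with exact IUPAC-degenerate matching.  Zero or multiple products raise.
    """
    seq = template.upper()
    if "-" in seq:
        raise ValueError("template must be gap-free")
    fwd_hits = _scan(primers.forward, seq)
    rev_rc = str(Seq(primers.reverse).reverse_complement())
    rev_hits = _scan(rev_rc, seq)
    products = []
    for f in fwd_hits:
        for r in rev_hits:
            end = r + len(rev_rc) - 1
            if end >= f + len(primers.forward):
                products.append((f, end))
    if len(products) != max_products:
        raise ValueError(
            f"in-silico PCR with {primers.name}: {len(products)} products "
            f"(expected {max_products})"
        )
    f, end = products[0]
    return Amplicon(sequence=seq[f - 1 : end], template_id="template", start=f, end=end)


def digest(amplicon: Amplicon | str, enzyme: Enzyme) -> FragmentPattern:
    """Fragment lengths induced by every top-strand cut; uncut -> one fragment.

    Lengths are measured between successive cut positions, ignoring 2-nt
    overhangs, which reproduces sizes as read from a gel.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon.upper()
    cuts = find_sites(seq, enzyme)
    bounds = [0] + cuts + [len(seq)]
    return FragmentPattern(tuple(b - a for a, b in zip(bounds, bounds[1:])))


@dataclass(frozen=True)
class CAPSCandidate:
    snp: SNPSite
    enzyme: Enzyme
    cut_allele: str        # base that completes the recognition site
    cut_race: str          # "E" or "Z": race whose allele is cut
    site_start_column: int  # alignment column where the recognition site begins


def diagnostic_caps_sites(
    panel: AlignedPanel,
    snps: Sequence[SNPSite],
    enzymes: Iterable[Enzyme] | None = None,
) -> list[CAPSCandidate]:
    """Fixed SNPs whose one allele completes a recognition site the other lacks.

    A candidate requires the recognition footprint (minus the SNP column) to be
    monomorphic across the whole panel, so the assay reads out only the
    diagnostic base.  SNPs where both alleles complete sites of the same
    enzyme are not diagnostic and are skipped.
    """
    enzymes = list(enzymes) if enzymes is not None else list(DEFAULT_ENZYMES.values())
    out: list[CAPSCandidate] = []
    for snp in snps:
        col = snp.column
        for enz in enzymes:
            k = len(enz.recognition)
            e_placements: list[int] = []  # site starts completed by the E allele
            z_placements: list[int] = []
            for site_start in range(max(1, col - k + 1), col + 1):
                if site_start + k - 1 > panel.length:
                    continue
                # context must be monomorphic (single unambiguous base) off the SNP
                context = []
                ok = True
                for c in range(site_start, site_start + k):
                    if c == col:
                        context.append(None)
                        continue
                    bases = {b for b in panel.column(c)}
                    if len(bases) != 1 or next(iter(bases)) not in BASES:
                        ok = False
                        break
                    context.append(next(iter(bases)))
                if not ok:
                    continue
                idx = col - site_start

                def completes(base: str) -> bool:
                    probe = context.copy()
                    probe[idx] = base
                    return iupac_match(enz.recognition, "".join(probe))

                if completes(snp.allele_e):
                    e_placements.append(site_start)
                if completes(snp.allele_z):
                    z_placements.append(site_start)
            # both alleles cut (even at shifted placements): a gel cannot
            # distinguish them, so the SNP is not diagnostic for this enzyme
            if bool(e_placements) == bool(z_placements):
                continue
            cut_allele, cut_race, placements = (
                (snp.allele_e, "E", e_placements)
                if e_placements
                else (snp.allele_z, "Z", z_placements)
            )
            for site_start in placements:
                out.append(CAPSCandidate(snp, enz, cut_allele, cut_race, site_start))
    return out


@dataclass(frozen=True)
class CAPSMarker:
    """A scorable CAPS marker with per-allele predicted fragment patterns.

    ``expected_pattern_*`` are the full digestion truth (every site in the
    amplicon).  ``nominal_pattern_*`` count only the diagnostic site, the
    convention assay tables use when a constitutive same-enzyme site (for
    instance one embedded in a primer) would add sub-resolution fragments;
    the two coincide for markers without constitutive sites.
    """

    name: str
    primers: PrimerPair
    enzyme: Enzyme
    snp_column: int
    cut_allele: str
    cut_race: str
    expected_pattern_cut: FragmentPattern
    expected_pattern_uncut: FragmentPattern
    nominal_pattern_cut: FragmentPattern | None = None
    nominal_pattern_uncut: FragmentPattern | None = None
    constitutive_site: bool = False  # amplicon carries a same-enzyme site in both alleles

    @property
    def uncut_race(self) -> str:
        return "Z" if self.cut_race == "E" else "E"


def _substitute(seq: str, pos0: int, base: str) -> str:
    return seq[:pos0] + base + seq[pos0 + 1 :]


def build_marker(
    panel: AlignedPanel,
    candidate: CAPSCandidate,
    primers: PrimerPair,
    name: str | None = None,
) -> CAPSMarker:
    """Predict both alleles' fragment patterns for a diagnostic candidate.

    The amplicon is taken from the ungapped panel consensus; each allele is
    substituted at the SNP and digested.  Identical patterns for the two
    alleles mean the assay cannot distinguish them and raise an error.  A
    same-enzyme site present under both alleles (e.g. one embedded in a primer)
    leaves the marker scorable but flags it.
    """
    snp = candidate.snp
    panel_consensus = panel.consensus()
    template = panel_consensus.replace("-", "")
    if snp.consensus_position is None:
        raise ValueError("SNP column maps to no consensus position")
    pos0 = snp.consensus_position - 1

    patterns = {}
    amplicons = {}
    for allele in (candidate.snp.allele_e, candidate.snp.allele_z):
        amp = insilico_pcr(_substitute(template, pos0, allele), primers)
        amplicons[allele] = amp
        patterns[allele] = digest(amp, candidate.enzyme)
    cut_allele = candidate.cut_allele
    uncut_allele = snp.allele_z if cut_allele == snp.allele_e else snp.allele_e
    pat_cut, pat_uncut = patterns[cut_allele], patterns[uncut_allele]
    if pat_cut == pat_uncut:
        raise ValueError(f"non-diagnostic: both alleles digest to {pat_cut}")
    constitutive = len(pat_uncut.fragment_lengths) > 1

    # fragments attributable to the diagnostic site alone (assay-table sizes)
    amp_cut = amplicons[cut_allele]
    site_cons = panel.column_to_consensus(candidate.site_start_column)
    L = len(amp_cut)
    nominal_uncut = FragmentPattern((L,))
    nominal_cut = nominal_uncut
    if site_cons is not None:
        cut_pos = site_cons - amp_cut.start + candidate.enzyme.cut_offset
        if 0 < cut_pos < L:
            nominal_cut = FragmentPattern((cut_pos, L - cut_pos))
    return CAPSMarker(
        name=name or f"{candidate.enzyme.name}@{snp.consensus_position}",
        primers=primers,
        enzyme=candidate.enzyme,
        snp_column=snp.column,
        cut_allele=cut_allele,
        cut_race=candidate.cut_race,
        expected_pattern_cut=pat_cut,
        expected_pattern_uncut=pat_uncut,
        nominal_pattern_cut=nominal_cut,
        nominal_pattern_uncut=nominal_uncut,
        constitutive_site=constitutive,
    )


# --- CSV I/O ---------------------------------------------------------------

def load_enzymes(path: str | Path) -> dict[str, Enzyme]:
    """Enzyme table CSV: name,recognition,cut_offset."""
    out: dict[str, Enzyme] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["name"]] = Enzyme(
                row["name"], row["recognition"], int(row["cut_offset"])
            )
    return out


def load_primers(path: str | Path) -> dict[str, PrimerPair]:
    """Primer table CSV: name,forward,reverse."""
    out: dict[str, PrimerPair] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["name"]] = PrimerPair(row["name"], row["forward"], row["reverse"])
    return out


def markers_to_rows(markers: Sequence[CAPSMarker]) -> list[dict]:
    return [
        {
            "name": m.name,
            "enzyme": m.enzyme.name,
            "primer_pair": m.primers.name,
            "snp_column": m.snp_column,
            "cut_allele": m.cut_allele,
            "cut_race": m.cut_race,
            "pattern_cut": str(m.expected_pattern_cut),
            "pattern_uncut": str(m.expected_pattern_uncut),
            "constitutive_site": m.constitutive_site,
        }
        for m in markers
    ]
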