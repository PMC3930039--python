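"""Fragment-pattern -> allele-call conversion and consensus diploid genotypes.

Observed gel patterns are matched to a marker's predicted cut/uncut patterns
within a size tolerance (default 5 bp, the resolution of sizing against a
50-bp ladder).  Per-marker calls are then combined into a consensus genotype;
individuals whose markers disagree are reported as discordant, never silently
resolved, because marker-vs-phenotype discrepancies are themselves a finding
(recombinants or assay failures).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .caps import CAPSMarker, FragmentPattern

CALLS = ("EE", "EZ", "ZZ")
DOSAGE_Z = {"EE": 0.0, "EZ": 0.5, "ZZ": 1.0}  # counts pgfar-z alleles / 2

__all__ = ["GenotypeCall", "call_marker", "consensus_genotype", "dosage"]


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    per_marker: dict
    consensus: str  # EE / EZ / ZZ / discordant / missing
    dosage: float | None  # z-allele dosage in {0, 0.5, 1}; None unless concordant


def _patterns_match(
    observed: Sequence[int], expected: FragmentPattern, tolerance: int, min_visible: int
) -> bool:
    """One-to-one match of observed lengths against gel-visible expected lengths."""
    exp = sorted(expected.visible(min_visible).fragment_lengths, reverse=True)
    obs = sorted(observed, reverse=True)
    if len(obs) != len(exp):
        return False
    return all(abs(o - e) <= tolerance for o, e in zip(obs, exp))


def _merge_patterns(a: FragmentPattern, b: FragmentPattern, tolerance: int) -> tuple[int, ...]:
    """Union of two patterns as seen on a heterozygote's gel lane.

    Fragments shared by both alleles (within tolerance) appear as one band.
    """
    merged = list(a.fragment_lengths)
    for x in b.fragment_lengths:
        if not any(abs(x - y) <= tolerance for y in merged):
            merged.append(x)
    return tuple(sorted(merged, reverse=True))


def call_marker(
    observed: Sequence[int] | FragmentPattern,
    marker: CAPSMarker,
    tolerance: int = 5,
    min_visible: int = 20,
) -> str:
    """Call EE/EZ/ZZ (or "missing") from an observed fragment pattern.

    Matching the cut pattern alone -> homozygote for the cut-allele race;
    the uncut pattern alone -> homozygote for the other race; the union of
    both -> heterozygote; anything else is unresolvable and returned missing.
    """
    obs = (
        list(observed.fragment_lengths)
        if isinstance(observed, FragmentPattern)
        else list(observed)
    )
    cut, uncut = marker.expected_pattern_cut, marker.expected_pattern_uncut
    if _patterns_match(obs, cut, tolerance, min_visible):
        return marker.cut_race * 2 if marker.cut_race == "E" else "ZZ"
    if _patterns_match(obs, uncut, tolerance, min_visible):
        return "EE" if marker.uncut_race == "E" else "ZZ"
    het = FragmentPattern(_merge_patterns(cut, uncut, tolerance))
    if _patterns_match(obs, het, tolerance, min_visible):
        return "EZ"
    return "missing"


def dosage(consensus: str, allele: str = "z") -> float | None:
    """Allele dosage of a concordant genotype (z-oriented by default)."""
    if consensus not in CALLS:
        return None
    d = DOSAGE_Z[consensus]
    return d if allele == "z" else 1.0 - d


def consensus_genotype(
    individual_id: str,
    calls: Mapping[str, str],
    resolve: str = "strict",
    dosage_allele: str = "z",
) -> GenotypeCall:
    """Combine per-marker calls into a consensus genotype.

    ``resolve="strict"`` (default) reports any disagreement among non-missing
    calls as ``discordant``; ``resolve="majority"`` takes a strict-majority
    call when one exists (still discordant on ties).
    """
    if resolve not in ("strict", "majority"):
        raise ValueError(f"unknown resolve mode {resolve!r}")
    informative = [c for c in calls.values() if c in CALLS]
    if not informative:
        cons = "missing"
    elif len(set(informative)) == 1:
        cons = informative[0]
    elif resolve == "majority":
        counts = Counter(informative).most_common()
        cons = (
            counts[0][0]
            if len(counts) == 1 or counts[0][1] > counts[1][1]
            else "discordant"
        )
    else:
        cons = "discordant"
    return GenotypeCall(
        individual_id=individual_id,
        per_marker=dict(calls),
        consensus=cons,
        dosage=dosage(cons, dosage_allele),
    )
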