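"""Synthetic-data generators with known ground truth for every pipeline stage.

Three generators mirror the three kinds of study input:

* :func:`simulate_panel` — aligned cDNA panels with planted race-fixed SNPs
  (inside or outside restriction-site contexts), optional divergent blocks and
  controlled within-group diversity;
* :func:`simulate_population` — site genotype samples under Hardy-Weinberg
  proportions, under inbreeding F, or as a two-deme admixture (which produces
  a Wahlund heterozygote deficit);
* :func:`simulate_phenotypes` — %E isomer values drawn per genotype class
  from truncated normal distributions.

Every generator is a pure function of its spec (including the seed) and
returns a truth record sufficient to score the corresponding detector.

:func:`pgfar_standin_panel` builds a synthetic stand-in for the published
cDNA panel, embedding the published primer pairs, diagnostic SNP coordinates
(857/995/1005) and enzyme-site geometry; see its docstring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .caps import DEFAULT_ENZYMES, Enzyme, PrimerPair, iupac_match
from .diversity import AlignedPanel, PanelRecord
from .genotyping import CALLS
from .phenotype import PhenotypeRecord
from .popgen import PopulationSample

__all__ = [
    "PanelSpec",
    "PopSpec",
    "PhenoSpec",
    "simulate_panel",
    "simulate_population",
    "simulate_phenotypes",
    "pgfar_standin_panel",
    "TABLE2_PRIMERS",
]

_BASES = "ACGT"

# Published primer pairs (degenerate W in the mnr primer).
TABLE2_PRIMERS = {
    "pgFAR-t": PrimerPair("pgFAR-t", "TTCGATTCGGGAACCCATA", "AGGTTCGCAACGTGGTCTAC"),
    "pgFAR-mn": PrimerPair(
        "pgFAR-mn", "GGGCAACAAAGGAGTCAAGGT", "CCAAAATATTTCCTGTATTTTAWGCA"
    ),
}


# ---------------------------------------------------------------------------
# aligned panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic aligned cDNA panel.

    Defaults emulate the published panel: 21 sequences, ~1.6-kb alignment,
    within-race diversity ~0.002 substitutions/site, three race-diagnostic
    SNPs planted inside restriction-site contexts plus a dozen plain fixed
    differences.
    """

    n_e: int = 10
    n_z: int = 11
    length: int = 1607
    within_group_diversity: float = 0.002
    n_diagnostic_snps: int = 3
    n_plain_snps: int = 12
    diagnostic_positions: tuple[int, ...] | None = None
    plain_positions: tuple[int, ...] | None = None
    divergent_block: tuple[int, int, float] | None = None  # (start, end, density)
    enzymes: tuple[str, ...] = ("TaqI", "NdeII", "MseI")
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=length)]


def _creates_site(seq: Sequence[str], pos0: int, enzymes: Sequence[Enzyme]) -> bool:
    """True if any enzyme site overlaps position pos0 (0-based)."""
    s = "".join(seq)
    for enz in enzymes:
        k = len(enz.recognition)
        for start in range(max(0, pos0 - k + 1), min(len(s) - k, pos0) + 1):
            if iupac_match(enz.recognition, s[start : start + k]):
                return True
    return False


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def simulate_panel(spec: PanelSpec) -> tuple[AlignedPanel, dict]:
    """Generate an aligned panel plus a truth record of everything planted.

    Diagnostic SNPs are planted so one race's allele completes the chosen
    enzyme's recognition site and the other race's allele breaks it, with a
    monomorphic recognition footprint.  Plain SNPs are race-fixed differences
    verified not to create any of the spec's enzyme sites under either allele.
    Within-group diversity is produced by singleton mutations at the expected
    density.  An explicit diagnostic/plain position collision raises.
    """
    rng = np.random.default_rng(spec.seed)
    enzymes = [DEFAULT_ENZYMES[name] for name in spec.enzymes]
    L = spec.length
    ancestral = _random_seq(rng, L)

    max_k = max(len(e.recognition) for e in enzymes)
    fixed_positions = spec.diagnostic_positions is not None
    if fixed_positions:
        diag_pos_wanted = list(spec.diagnostic_positions)
        if len(diag_pos_wanted) != spec.n_diagnostic_snps:
            raise ValueError("diagnostic_positions length mismatch")
    else:
        diag_pos_wanted = [None] * spec.n_diagnostic_snps  # drawn below
    plain_pos = list(spec.plain_positions) if spec.plain_positions is not None else []
    if set(p for p in diag_pos_wanted if p) & set(plain_pos):
        raise ValueError("diagnostic site collides with plain SNP")

    cons_e = ancestral.copy()
    cons_z = ancestral.copy()
    protected: set[int] = set()  # 0-based columns that later mutations must avoid
    truth_diag = []
    diag_pos: list[int] = []

    def try_plant(i: int, pos: int) -> bool:
        """Plant diagnostic SNP i at 1-based pos; rolls back and returns False
        when no allele choice leaves the site cleanly diagnostic."""
        enz = enzymes[i % len(enzymes)]
        rec = enz.recognition
        snp_idx = int(rng.integers(0, len(rec)))
        site_start0 = pos - 1 - snp_idx
        if site_start0 < max_k or site_start0 + len(rec) + max_k > L:
            return False
        span = set(range(site_start0 - max_k, site_start0 + len(rec) + max_k))
        if span & protected:
            return False
        backup_e = cons_e[site_start0 : site_start0 + len(rec)]
        backup_z = cons_z[site_start0 : site_start0 + len(rec)]
        cut_race = "E" if i % 2 == 0 else "Z"
        complete = rec[snp_idx]  # concrete for the default enzymes
        for j, ch in enumerate(rec):
            cons_e[site_start0 + j] = ch
            cons_z[site_start0 + j] = ch
        cut_cons, uncut_cons = (cons_e, cons_z) if cut_race == "E" else (cons_z, cons_e)
        cut_cons[pos - 1] = complete
        # broken base must not complete this enzyme at another placement nor
        # any other enzyme's site overlapping the SNP, under either allele
        others = [e for e in enzymes if e.name != enz.name]
        broken = None
        if not _creates_site(cut_cons, pos - 1, others):
            for cand_base in rng.permutation([b for b in _BASES if b != complete]):
                uncut_cons[pos - 1] = cand_base
                if _creates_site(uncut_cons, pos - 1, enzymes):
                    continue
                broken = cand_base
                break
        if broken is None:
            cons_e[site_start0 : site_start0 + len(rec)] = backup_e
            cons_z[site_start0 : site_start0 + len(rec)] = backup_z
            return False
        uncut_cons[pos - 1] = broken
        protected.update(span)
        diag_pos.append(pos)
        truth_diag.append(
            {
                "position": pos,
                "enzyme": enz.name,
                "cut_race": cut_race,
                "allele_e": cons_e[pos - 1],
                "allele_z": cons_z[pos - 1],
            }
        )
        return True

    for i, wanted in enumerate(diag_pos_wanted):
        if wanted is not None:
            if not try_plant(i, wanted):
                raise ValueError(f"cannot place a clean diagnostic SNP at {wanted}")
        else:
            for _ in range(200):
                pos = int(rng.integers(2 * max_k, L - 2 * max_k))
                if try_plant(i, pos):
                    break
            else:
                raise ValueError("could not place diagnostic SNPs; panel too short?")
    diag_pos.sort()
    truth_diag.sort(key=lambda d: d["position"])

    # remove accidental enzyme sites outside planted contexts; the same
    # replacement is applied to both group consensuses so scrubbing never
    # introduces spurious fixed differences
    def scrub_joint() -> bool:
        changed = False
        for consensus in (cons_e, cons_z):
            s = "".join(consensus)
            for enz in enzymes:
                k = len(enz.recognition)
                for start in range(len(s) - k + 1):
                    if not iupac_match(enz.recognition, s[start : start + k]):
                        continue
                    span = set(range(start, start + k))
                    if span & protected:
                        continue
                    new = _other_base(rng, consensus[start])
                    cons_e[start] = new
                    cons_z[start] = new
                    s = "".join(consensus)
                    changed = True
        return changed

    for _ in range(8):
        if not scrub_joint():
            break

    # plain fixed differences (outside any enzyme-site context, both alleles)
    want = spec.n_plain_snps
    attempts = 0
    while len(plain_pos) < want:
        attempts += 1
        if attempts > 50 * want + 100:
            raise ValueError("could not place plain SNPs without creating enzyme sites")
        pos = int(rng.integers(max_k + 1, L - max_k))
        if pos in diag_pos or pos in plain_pos or (pos - 1) in protected:
            continue
        alt = _other_base(rng, cons_e[pos - 1])
        trial_z = cons_z.copy()
        trial_z[pos - 1] = alt
        if _creates_site(cons_e, pos - 1, enzymes) or _creates_site(trial_z, pos - 1, enzymes):
            continue
        cons_z[pos - 1] = alt
        plain_pos.append(pos)
        protected.add(pos - 1)
    for pos in plain_pos:
        protected.add(pos - 1)
        if cons_e[pos - 1] == cons_z[pos - 1]:  # explicitly supplied positions
            alt = _other_base(rng, cons_e[pos - 1])
            trial_z = cons_z.copy()
            trial_z[pos - 1] = alt
            if _creates_site(cons_e, pos - 1, enzymes) or _creates_site(trial_z, pos - 1, enzymes):
                raise ValueError(f"plain SNP at {pos} would create an enzyme site")
            cons_z[pos - 1] = alt

    block = spec.divergent_block
    block_positions: list[int] = []
    if block is not None:
        bstart, bend, density = block
        for pos in range(bstart, bend + 1):
            if (pos - 1) in protected or pos in diag_pos or pos in plain_pos:
                continue
            if rng.random() < density:
                cons_z[pos - 1] = _other_base(rng, cons_e[pos - 1])
                block_positions.append(pos)
                protected.add(pos - 1)

    protected.update(p - 1 for p in diag_pos)

    def expand(consensus: list[str], n: int, prefix: str, group: str) -> list[PanelRecord]:
        # singleton mutations to hit within-group diversity in expectation:
        # a singleton adds 2/(n*L) to mean pairwise diversity
        n_mut = 0
        if n >= 2 and spec.within_group_diversity > 0:
            n_mut = int(round(spec.within_group_diversity * L * n / 2))
        seqs = [consensus.copy() for _ in range(n)]
        placed = 0
        guard = 0
        while placed < n_mut:
            guard += 1
            if guard > 100 * n_mut + 100:
                break
            pos0 = int(rng.integers(0, L))
            if pos0 in protected:
                continue
            carrier = int(rng.integers(0, n))
            seqs[carrier][pos0] = _other_base(rng, consensus[pos0])
            placed += 1
        return [
            PanelRecord(f"{prefix}{i + 1:02d}", group, "".join(s))
            for i, s in enumerate(seqs)
        ]

    records = expand(cons_e, spec.n_e, "E", "E") + expand(cons_z, spec.n_z, "Z", "Z")
    truth = {
        "diagnostic_snps": truth_diag,
        "plain_snps": sorted(plain_pos),
        "divergent_block": None if block is None else list(block[:2]),
        "block_positions": sorted(block_positions),
        "seed": spec.seed,
    }
    return AlignedPanel(records), truth


# ---------------------------------------------------------------------------
# published-assay stand-in panel
# ---------------------------------------------------------------------------

def pgfar_standin_panel(
    n_e: int = 10, n_z: int = 11, seed: int = 0
) -> tuple[AlignedPanel, dict]:
    """SYNTHETIC stand-in for the published pgfar cDNA panel.

    The true GenBank panel is not redistributed here; this generator builds a
    synthetic alignment that embeds every published assay constraint that a
    colinear template can satisfy: the two published primer pairs, diagnostic
    SNPs at consensus positions 857 (TaqI, z-allele cut), 995 (NdeII, e-allele
    cut) and 1005 (MseI, e-allele cut) with the published alleles, a 150-bp
    TaqI amplicon and a 145-bp NdeII/MseI amplicon, the TaqI diagnostic cut at
    118/32 and the NdeII cut at 83/62.  The published MseI sizes (93+52) and
    NdeII sizes cannot be realised simultaneously on one colinear template
    (the cuts sit 12 bp apart in cDNA coordinates but 10 bp apart in the
    published sizes), so MseI here digests to 95+50 — within gel-calling
    tolerance of the published values.  Note also that the published forward
    TaqI primer itself contains a TCGA site, so full digestion adds a 2-bp
    terminal fragment invisible on a gel.
    """
    rng = np.random.default_rng(seed)
    L = 1200
    tmpl = _random_seq(rng, L)

    tf, tr = TABLE2_PRIMERS["pgFAR-t"].forward, TABLE2_PRIMERS["pgFAR-t"].reverse
    mnf = TABLE2_PRIMERS["pgFAR-mn"].forward
    # the degenerate W in the mnr primer is T on this template: with A the
    # primer's 3' TTAW would itself become an MseI site
    mnr = TABLE2_PRIMERS["pgFAR-mn"].reverse.replace("W", "T")

    def paste(pos1: int, seq: str) -> None:
        for j, ch in enumerate(seq):
            tmpl[pos1 - 1 + j] = ch

    # TaqI amplicon 740..889 (150 bp): forward primer at 740, reverse footprint at 870
    paste(740, tf)
    paste(870, str(Seq(tr).reverse_complement()))
    # diagnostic TaqI site at 857..860, SNP at 857 (Z allele T completes TCGA)
    paste(857, "TCGA")
    # NdeII/MseI amplicon 910..1054 (145 bp)
    paste(910, mnf)
    paste(1029, str(Seq(mnr).reverse_complement()))
    paste(993, "GATC")  # SNP at 995 (E allele T); cut after 992 -> 83+62
    paste(1004, "TTAA")  # SNP at 1005 (E allele T); cut after 1004 -> 95+50

    # scrub accidental recognition sites inside the amplicons (the primer-embedded
    # TaqI TCGA at 741..744 is part of the published primer and must stay)
    planted = {(857, "TaqI"), (993, "NdeII"), (1004, "MseI"), (741, "TaqI")}
    fixed_spans = set()
    for start, seq in ((740, tf), (870, tr), (910, mnf), (1029, mnr), (857, "TCGA"),
                       (993, "GATC"), (1004, "TTAA")):
        fixed_spans.update(range(start, start + len(seq)))
    for lo, hi, enz_names in ((740, 889, ("TaqI",)), (910, 1054, ("NdeII", "MseI"))):
        changed = True
        while changed:
            changed = False
            s = "".join(tmpl)
            for name in enz_names:
                enz = DEFAULT_ENZYMES[name]
                k = len(enz.recognition)
                for start in range(lo, hi - k + 2):
                    if (start, name) in planted:
                        continue
                    if iupac_match(enz.recognition, s[start - 1 : start - 1 + k]):
                        for col in range(start, start + k):
                            if col not in fixed_spans:
                                tmpl[col - 1] = _other_base(rng, tmpl[col - 1])
                                changed = True
                                break
                        else:  # fully inside fixed sequence: genuinely constitutive
                            continue
                        break
                if changed:
                    break

    cons_z = tmpl.copy()
    cons_e = tmpl.copy()
    # published alleles: E = G857 T995 T1005, Z = T857 G995 G1005
    cons_z[857 - 1], cons_e[857 - 1] = "T", "G"
    cons_e[995 - 1], cons_z[995 - 1] = "T", "G"
    cons_e[1005 - 1], cons_z[1005 - 1] = "T", "G"

    # a scatter of plain race-fixed differences outside the amplicons,
    # approximating the published between-race divergence
    protected = set(range(735, 1060))
    plain = []
    while len(plain) < 12:
        pos = int(rng.integers(10, L - 10))
        if pos in protected or (pos - 1) in [p - 1 for p in plain]:
            continue
        cons_z[pos - 1] = _other_base(rng, cons_e[pos - 1])
        plain.append(pos)
        protected.update(range(pos - 4, pos + 4))

    def expand(consensus, n, prefix, group):
        n_mut = int(round(0.002 * L * n / 2))
        seqs = [consensus.copy() for _ in range(n)]
        placed = 0
        while placed < n_mut:
            pos0 = int(rng.integers(0, L))
            if pos0 + 1 in protected or pos0 in protected:
                continue
            seqs[int(rng.integers(0, n))][pos0] = _other_base(rng, consensus[pos0])
            placed += 1
        return [
            PanelRecord(f"{prefix}{i + 1:02d}", group, "".join(s))
            for i, s in enumerate(seqs)
        ]

    records = expand(cons_e, n_e, "synE", "E") + expand(cons_z, n_z, "synZ", "Z")
    truth = {
        "diagnostic_snps": [
            {"position": 857, "enzyme": "TaqI", "cut_race": "Z", "allele_e": "G", "allele_z": "T"},
            {"position": 995, "enzyme": "NdeII", "cut_race": "E", "allele_e": "T", "allele_z": "G"},
            {"position": 1005, "enzyme": "MseI", "cut_race": "E", "allele_e": "T", "allele_z": "G"},
        ],
        "plain_snps": sorted(plain),
        "amplicons": {"pgFAR-t": (740, 889), "pgFAR-mn": (910, 1054)},
        "cds_columns": (1, L - L % 3),
        "seed": seed,
    }
    return AlignedPanel(records), truth


# ---------------------------------------------------------------------------
# population genotype samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopSpec:
    """Genotype-sample spec: HWE (default), inbreeding F, or two-deme admixture."""

    n: int = 48
    p_e: float = 0.2
    inbreeding_F: float = 0.0
    admixture: tuple[float, float, float] | None = None  # (p_e deme1, p_e deme2, weight deme1)
    discordance_rate: float = 0.0
    site_id: str = "sim"
    region: str | None = None
    seed: int = 0


def genotype_probabilities(p_e: float, F: float = 0.0) -> tuple[float, float, float]:
    """(P(zz), P(ez), P(ee)) under inbreeding coefficient F."""
    q = 1.0 - p_e
    probs = (q * q + F * p_e * q, 2 * p_e * q * (1 - F), p_e * p_e + F * p_e * q)
    if min(probs) < -1e-12:
        raise ValueError(f"negative genotype probability under F={F}, p={p_e}")
    return tuple(max(x, 0.0) for x in probs)  # type: ignore[return-value]


def simulate_population(spec: PopSpec) -> tuple[PopulationSample, list[dict]]:
    """Draw a genotype sample; returns counts plus per-individual records.

    Under ``admixture=(p1, p2, w)`` each individual's deme is Bernoulli(w) and
    its genotype Hardy-Weinberg within the deme, producing a Wahlund
    heterozygote deficit in the pooled counts.  ``discordance_rate`` flips the
    TaqI call of that fraction of individuals (heterozygotes are recorded as
    ZZ at TaqI, mirroring the discrepancy class seen in the study; other
    genotypes get a discordant EZ call), leaving NdeII/MseI at the truth.
    """
    rng = np.random.default_rng(spec.seed)
    genos = []
    if spec.admixture is not None:
        p1, p2, w = spec.admixture
        demes = rng.random(spec.n) < w
        for in_first in demes:
            probs = genotype_probabilities(p1 if in_first else p2)
            genos.append(int(rng.choice(3, p=probs)))  # 0=zz 1=ez 2=ee
    else:
        probs = genotype_probabilities(spec.p_e, spec.inbreeding_F)
        genos = list(rng.choice(3, size=spec.n, p=probs))
    code = {0: "ZZ", 1: "EZ", 2: "EE"}
    individuals = []
    for i, g in enumerate(genos):
        true_call = code[int(g)]
        per_marker = {"TaqI": true_call, "NdeII": true_call, "MseI": true_call}
        discordant = rng.random() < spec.discordance_rate
        if discordant:
            per_marker["TaqI"] = "ZZ" if true_call == "EZ" else "EZ"
        individuals.append(
            {
                "individual_id": f"{spec.site_id}-{i + 1:03d}",
                "true_genotype": true_call,
                "per_marker": per_marker,
                "discordant": discordant,
            }
        )
    sample = PopulationSample(
        spec.site_id,
        n_zz=sum(1 for g in genos if g == 0),
        n_ez=sum(1 for g in genos if g == 1),
        n_ee=sum(1 for g in genos if g == 2),
        region=spec.region,
    )
    return sample, individuals


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenoSpec:
    """Class-conditional %E distributions; defaults are the study's estimates."""

    mean_ee: float = 98.02
    sd_ee: float = 4.24
    mean_ez: float = 67.58
    sd_ez: float = 8.92
    mean_zz: float = 2.74
    sd_zz: float = 6.24
    unresolved_rate: float = 0.0
    seed: int = 0


def simulate_phenotypes(
    genotypes: Sequence[tuple[str, str]] | Sequence[str],
    spec: PhenoSpec = PhenoSpec(),
    family: str = "sim",
    rng: np.random.Generator | None = None,
) -> list[PhenotypeRecord]:
    """%E values per genotype from truncated normals on [0, 100].

    ``genotypes`` is a sequence of EE/EZ/ZZ calls or (individual_id, call)
    pairs.  ``unresolved_rate`` of records get no GC reading (pct_E None).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    params = {
        "EE": (spec.mean_ee, spec.sd_ee),
        "EZ": (spec.mean_ez, spec.sd_ez),
        "ZZ": (spec.mean_zz, spec.sd_zz),
    }
    out = []
    for i, item in enumerate(genotypes):
        ind_id, call = item if isinstance(item, tuple) else (f"{family}-{i + 1:03d}", item)
        if call not in CALLS:
            raise ValueError(f"unknown genotype {call!r}")
        mu, sd = params[call]
        if rng.random() < spec.unresolved_rate:
            pct = None
        elif sd == 0:
            pct = mu
        else:
            a, b = (0 - mu) / sd, (100 - mu) / sd
            pct = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        out.append(PhenotypeRecord(ind_id, family, pct))
    return out
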