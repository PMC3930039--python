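"""Pheromone phenotype classification and genotype-phenotype association.

Female phenotype is the percentage of the E11-14:OAc isomer in the pheromone
gland extract.  Classes follow the study's cutoffs: >=90% E isomer is class
1.0 (E-type blend), <=5% is class 3.0 (Z-type), everything between is 2.0
(hybrid-type); missing GC readings are unresolved ("U").

Association is quantified by Pearson product-moment correlation, in two
codings that are both reported:

* variant ``a`` (continuous): %E against the count of pgfar-e alleles (0/1/2);
* variant ``b`` (class codes): phenotype class (1/2/3) against z-allele dosage
  (0/0.5/1), the discrete coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

E_ALLELE_COUNT = {"EE": 2, "EZ": 1, "ZZ": 0}

__all__ = [
    "PhenotypeRecord",
    "classify_phenotype",
    "pmcc",
    "association_report",
    "genotype_class_summary",
    "chi_square_genotypes",
]


@dataclass(frozen=True)
class PhenotypeRecord:
    individual_id: str
    family: str
    pct_E: float | None  # None = unresolved GC reading
    pheno_class: float | str = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pheno_class is None:
            object.__setattr__(self, "pheno_class", classify_phenotype(self.pct_E))


def classify_phenotype(pct_E: float | None) -> float | str:
    """Class 1.0 (>=90% E), 3.0 (<=5% E), 2.0 otherwise, "U" if unresolved."""
    if pct_E is None or (isinstance(pct_E, float) and math.isnan(pct_E)):
        return "U"
    if not 0 <= pct_E <= 100:
        raise ValueError(f"pct_E {pct_E} outside [0, 100]")
    if pct_E >= 90:
        return 1.0
    if pct_E <= 5:
        return 3.0
    return 2.0


def pmcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _variant_a(pct_E: Sequence[float], genotypes: Sequence[str]) -> float:
    counts = [E_ALLELE_COUNT[g] for g in genotypes]
    return pmcc(pct_E, counts)


def _variant_b(pct_E: Sequence[float], genotypes: Sequence[str]) -> float:
    classes = [classify_phenotype(p) for p in pct_E]
    if any(c == "U" for c in classes):
        raise ValueError("unresolved phenotypes in variant-b input")
    dos = [{"EE": 0.0, "EZ": 0.5, "ZZ": 1.0}[g] for g in genotypes]
    return pmcc(classes, dos)


def association_report(
    records: Iterable[PhenotypeRecord],
    genotypes: Mapping[str, str],
) -> pd.DataFrame:
    """Per-family and pooled correlations, both codings, signed and |r|.

    ``genotypes`` maps individual_id -> EE/EZ/ZZ consensus call.  Unresolved
    phenotypes, missing/discordant genotypes are excluded.  The pooled row
    also carries the unweighted mean +/- SD of per-family coefficients.
    """
    rows = [
        (r.family, r.individual_id, r.pct_E, genotypes[r.individual_id])
        for r in records
        if r.pct_E is not None and genotypes.get(r.individual_id) in E_ALLELE_COUNT
    ]
    if not rows:
        raise ValueError("degenerate input: no scorable individuals")
    df = pd.DataFrame(rows, columns=["family", "individual_id", "pct_E", "genotype"])
    out = []
    for fam, sub in df.groupby("family"):
        out.append(_assoc_row(str(fam), sub))
    pooled = _assoc_row("pooled", df)
    fam_rs = [r["r_continuous"] for r in out if r["r_continuous"] is not None]
    if fam_rs:
        pooled["family_mean_r"] = float(np.mean(fam_rs))
        pooled["family_sd_r"] = float(np.std(fam_rs, ddof=1)) if len(fam_rs) > 1 else None
    out.append(pooled)
    return pd.DataFrame(out)


def _assoc_row(label: str, sub: pd.DataFrame) -> dict:
    row: dict = {"family": label, "n": len(sub)}
    for key, fn in (("r_continuous", _variant_a), ("r_class", _variant_b)):
        try:
            r = fn(sub["pct_E"].tolist(), sub["genotype"].tolist())
        except ValueError:
            r = None
        row[key] = r
        row[f"abs_{key}"] = abs(r) if r is not None else None
    return row


def genotype_class_summary(
    records: Iterable[PhenotypeRecord], genotypes: Mapping[str, str]
) -> pd.DataFrame:
    """Mean +/- sample SD (n-1) of %E per consensus genotype class."""
    by_geno: dict[str, list[float]] = {g: [] for g in ("EE", "EZ", "ZZ")}
    for r in records:
        g = genotypes.get(r.individual_id)
        if r.pct_E is not None and g in by_geno:
            by_geno[g].append(r.pct_E)
    rows = []
    for g, vals in by_geno.items():
        rows.append(
            {
                "genotype": g,
                "n": len(vals),
                "mean_pct_E": float(np.mean(vals)) if vals else None,
                "sd_pct_E": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            }
        )
    return pd.DataFrame(rows)


def chi_square_genotypes(
    observed: Sequence[float], expected: Sequence[float], df: int | None = None
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square: sum (O-E)^2/E with upper-tail p."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same categories")
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    dof = df if df is not None else len(obs) - 1
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    return chi2, dof, p
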