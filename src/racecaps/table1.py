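"""Printed field-survey values (per-site sample sizes, H_O, H_E, HWE p).

These are the published per-site summaries for the 16 light-trap collections
plus the E-race control colony, used as inputs: genotype counts are not given
directly, so they are recovered from (n, H_O, H_E) via
:func:`racecaps.popgen.reconstruct_counts`.  ``h_e`` / ``p_value`` are None
for monomorphic sites; p-values printed as "<0.001" are stored as the string
"<0.001" alongside a numeric bound.
"""

from __future__ import annotations

from dataclasses import dataclass

from .popgen import PopulationSample, reconstruct_counts

__all__ = ["SiteRow", "TABLE1", "MIDWEST_SITES", "EASTCOAST_SITES", "table1_samples"]


@dataclass(frozen=True)
class SiteRow:
    site_id: str
    name: str
    state: str
    region: str
    n_male: int
    n_female: int
    h_o: float
    h_e: float | None
    p_value: float | None  # None: monomorphic; 0.001 with p_censored: printed "<0.001"
    p_censored: bool = False

    @property
    def n(self) -> int:
        return self.n_male + self.n_female


TABLE1: list[SiteRow] = [
    SiteRow("1", "Mead", "NE", "Midwest", 24, 24, 0.000, None, None),
    SiteRow("2", "Brookings", "SD", "Midwest", 12, 12, 0.000, None, None),
    SiteRow("3", "Kanawha", "IA", "Midwest", 24, 24, 0.000, None, None),
    SiteRow("4", "Crawfordsville", "IA", "Midwest", 24, 24, 0.000, None, None),
    SiteRow("5", "Lexington", "KY", "Midwest", 10, 14, 0.000, None, None),
    SiteRow("6", "Snyder Co.", "PA", "EastCoast", 13, 11, 0.083, 0.156, 0.126),
    SiteRow("7", "Beltsville", "MD", "EastCoast", 17, 14, 0.419, 0.337, 0.295),
    SiteRow("8", "Newark", "DE", "EastCoast", 44, 44, 0.193, 0.347, 0.001, True),
    SiteRow("9", "Cohansey", "NJ", "EastCoast", 24, 24, 0.125, 0.281, 0.001, True),
    SiteRow("10", "Sergentsville", "NJ", "EastCoast", 11, 13, 0.208, 0.311, 0.152),
    SiteRow("11", "Little York", "NJ", "EastCoast", 24, 24, 0.125, 0.118, 1.000),
    SiteRow("12", "Yates", "NY", "EastCoast", 3, 7, 0.200, 0.506, 0.082),
    SiteRow("13", "Aurora", "NY", "EastCoast", 10, 7, 0.059, 0.059, 1.000),
    SiteRow("14", "Spencer", "NY", "EastCoast", 9, 11, 0.100, 0.097, 1.000),
    SiteRow("15", "Freeville", "NY", "EastCoast", 5, 6, 0.182, 0.173, 1.000),
    SiteRow("16", "Hartford", "NY", "EastCoast", 6, 4, 0.000, None, None),
    SiteRow("C", "BENY colony", "NY", "Colony", 0, 44, 0.000, None, None),
]

MIDWEST_SITES = [r.site_id for r in TABLE1 if r.region == "Midwest"]
EASTCOAST_SITES = [r.site_id for r in TABLE1 if r.region == "EastCoast"]


def table1_samples(include: list[str] | None = None) -> list[PopulationSample]:
    """Genotype-count samples reconstructed from the printed per-site values.

    The BENY colony row is all-EE (the pure E-race control); field monomorphic
    rows are all-ZZ, matching the fixed pgfar-z Midwest populations.
    """
    out = []
    for row in TABLE1:
        if include is not None and row.site_id not in include:
            continue
        if row.site_id == "C":
            counts = (0, 0, row.n)  # E-race colony: fixed pgfar-e
        else:
            counts = reconstruct_counts(row.n, row.h_o, row.h_e)
        out.append(PopulationSample(row.site_id, *counts, region=row.region))
    return out
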