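import numpy as np
import pytest

from racecaps.caps import build_marker, diagnostic_caps_sites
from racecaps.diversity import AlignedPanel, PanelRecord, fixed_differences
from racecaps.simulate import TABLE2_PRIMERS, pgfar_standin_panel


def make_panel(rows, groups=None):
    """Build a small panel from (id, group, seq) tuples or plain sequences."""
    records = []
    for i, row in enumerate(rows):
        if isinstance(row, str):
            group = (groups or {}).get(i, "unlabeled")
            records.append(PanelRecord(f"s{i + 1}", group, row))
        else:
            records.append(PanelRecord(*row))
    return AlignedPanel(records)


@pytest.fixture(scope="session")
def standin():
    """Synthetic stand-in for the published cDNA panel (see its docstring)."""
    return pgfar_standin_panel(seed=0)


@pytest.fixture(scope="session")
def standin_markers(standin):
    """The three published-geometry CAPS markers built from the stand-in."""
    panel, truth = standin
    snps = fixed_differences(panel, cds_columns=truth["cds_columns"])
    cands = diagnostic_caps_sites(panel, snps)
    markers = {}
    for cand in cands:
        for primers in TABLE2_PRIMERS.values():
            try:
                m = build_marker(panel, cand, primers)
            except ValueError:
                continue
            markers[m.enzyme.name] = m
            break
    assert set(markers) == {"TaqI", "NdeII", "MseI"}
    return markers


def neutral_panel(seed, n=10, length=500, mu=0.005):
    """Neutral panmictic panel via the coalescent (independent of the package)."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0, sequence_length=length,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 1)
    mat = np.full((n, length), "A", dtype="U1")
    for var in mts.variants():
        col = int(var.site.position)
        alleles = np.array(var.alleles, dtype="U1")
        mat[:, col] = alleles[var.genotypes]
    return make_panel(["".join(row) for row in mat])
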