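import numpy as np
import pandas as pd
import pytest

from hma_fidelity.tables import PairingMap, SampleMeta, TaxonTable


def make_table(values, taxa=None, samples=None, rank="species"):
    """TaxonTable from a nested list (taxa x samples)."""
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return TaxonTable(pd.DataFrame(values, index=taxa, columns=samples), rank=rank)


def human(sample_id, donor_id, timepoint="T0", study="st1"):
    return SampleMeta(sample_id, "human", donor_id, timepoint, study, "none", "")


def mouse(sample_id, donor_id, group, timepoint="T0", study="st1", route="HTR"):
    return SampleMeta(sample_id, "mouse", donor_id, timepoint, study, route, group)


@pytest.fixture
def two_donor_cohort():
    """2 donors, 3 mice each, hand-enumerable."""
    meta = [human("h1", "d1"), human("h2", "d2")]
    members = {}
    for d in ("d1", "d2"):
        group = f"{d}_mice"
        members[group] = set()
        for j in range(3):
            sid = f"{d}_m{j}"
            meta.append(mouse(sid, d, group))
            members[group].add(sid)
    pairing = PairingMap([("h1", "d1_mice"), ("h2", "d2_mice")], members)
    return meta, pairing
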