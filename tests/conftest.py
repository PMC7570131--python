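"""Shared fixtures: a moderate truth-known simulation processed end-to-end."""

import numpy as np
import pandas as pd
import pytest

import hmpenrich as he
from hmpenrich.counts import from_simulation, cpm


def make_metadata(n: int = 24) -> pd.DataFrame:
    """The 8/6/4/6 four-genotype sibling layout used across tests."""
    meta = pd.DataFrame(
        {
            "genotype": (["wildtype"] * 8 + ["eofad_het"] * 6
                         + ["null_het"] * 4 + ["trans_het"] * 6),
            "sex": ["female", "male"] * 12,
            "tank": [f"tank{i % 3 + 1}" for i in range(24)],
        },
        index=[f"S{i + 1:02d}" for i in range(24)],
    )
    return meta.iloc[:n]


@pytest.fixture(scope="session")
def planted_sim():
    """Simulation with planted coordinated set shifts and large-effect genes."""
    cfg = he.SimConfig(
        n_genes=3000,
        n_sets=30,
        set_size_range=(15, 80),
        seed=101,
        lib_size_range=(4e5, 8e5),
        n_de_genes=4,
        perturbed_sets=[
            he.PerturbedSet("KEGG_SET_0001", ("trans_het",), 0.4, 0.8),
            he.PerturbedSet("HALLMARK_SET_0002", ("eofad_het", "null_het"), -0.4, 0.8),
        ],
    )
    sets = he.generate_gene_sets(cfg)
    tables, meta, truth = he.generate_counts(cfg, gene_sets=sets)
    return {"config": cfg, "sets": sets, "tables": tables,
            "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def processed(planted_sim):
    """Filtered + TMM-normalized gene-level count matrix."""
    table = from_simulation(planted_sim["tables"])
    m = he.aggregate_to_genes(table, metadata=planted_sim["meta"])
    m = he.filter_undetected(m)
    return he.tmm_normalize(m)


@pytest.fixture(scope="session")
def two_pass(processed, planted_sim):
    """Initial DE fit, RUV factors, and the final DE fit with W1."""
    meta = planted_sim["meta"]
    factors, de0 = he.ruv_two_pass(
        processed, meta, k=1,
        n_controls=min(2000, processed.counts.shape[0]),
    )
    design = he.DesignSpec.from_metadata(meta, W=factors.W)
    disp = he.estimate_dispersions(processed, design)
    de = he.fit_and_test(processed, design, disp)
    return {"factors": factors, "de0": de0, "design": design, "de": de}


@pytest.fixture(scope="session")
def enrichment_state(processed, planted_sim, two_pass):
    logcpm = cpm(processed, log=True)
    sets_r = planted_sim["sets"].restrict_to_universe(list(processed.counts.index))
    ranked = {c: he.rank_genes(two_pass["de"], c) for c in he.CONTRASTS}
    return he.EnrichmentState(
        logcpm=logcpm, design=two_pass["design"], ranked=ranked,
        sets=sets_r, n_perm=999, n_rot=999,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
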