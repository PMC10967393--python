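"""Shared fixtures: a small synthetic cohort carried through the network
pipeline once per session, so individual tests stay fast."""

import numpy as np
import pandas as pd
import pytest

from lncnet import module_analysis as ma
from lncnet import network as nw
from lncnet.expression import log_transform, threshold_genes, tpm_normalize
from lncnet.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(seed=11, n_patients=80, n_genes=1000, n_modules=4,
                       module_sizes=(150, 100, 80, 60))
    annotation, meta, counts, truth = generate_cohort(cfg)
    return cfg, annotation, meta, counts, truth


@pytest.fixture(scope="session")
def small_logtpm(small_cohort):
    _, annotation, _, counts, _ = small_cohort
    retained, _ = threshold_genes(counts, annotation=annotation)
    tpm = tpm_normalize(counts, annotation.set_index("gene_id")["length"], retained)
    return log_transform(tpm)


@pytest.fixture(scope="session")
def small_network(small_cohort, small_logtpm):
    resid = nw.regress_covariates(small_logtpm, ["batch"])
    net = nw.adjacency(resid, 6)
    nw.tom(net)
    assignment = nw.detect_modules(net.dissimilarity, net.genes)
    return resid, net, assignment


@pytest.fixture(scope="session")
def small_modules(small_network):
    resid, net, assignment = small_network
    mes = ma.eigengenes(resid, assignment)
    merged, mes, _ = ma.merge_modules(mes, assignment, resid)
    return resid, net, merged, mes


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def toy_annotation(records):
    """Build a small annotation table from (gene_id, biotype, chrom, start, end)."""
    from lncnet.annotation import make_annotation
    return make_annotation(pd.DataFrame(
        records, columns=["gene_id", "biotype", "chrom", "start", "end"]))
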