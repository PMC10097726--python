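import numpy as np
import pandas as pd
import pytest

from ricproteo.datatypes import QuantMatrix, SampleInfo
from ricproteo.diffexp import EnrichmentModel
from ricproteo.simulate import SimConfig, simulate_eric_experiment


def make_samples(n_plus=2, n_minus=1, tissue="liver", assay="eric", batch="b1"):
    samples = []
    for r in range(1, n_plus + 1):
        samples.append(
            SampleInfo(f"{tissue}_{assay}_plusUV_r{r}", tissue, assay, "plusUV", r, batch)
        )
    for r in range(1, n_minus + 1):
        samples.append(
            SampleInfo(f"{tissue}_{assay}_minusUV_r{r}", tissue, assay, "minusUV", r, batch)
        )
    return samples


def make_quant(values, samples, peptides=None, mass=None):
    values = np.asarray(values, float)
    proteins = pd.Index([f"P{i:03d}" for i in range(values.shape[0])], name="accession")
    if peptides is None:
        peptides = np.full(values.shape[0], 3)
    return QuantMatrix(
        intensity=pd.DataFrame(values, index=proteins, columns=[s.sample_id for s in samples]),
        samples=list(samples),
        unique_peptides=pd.Series(peptides, index=proteins),
        predicted_mass_kda=None if mass is None else pd.Series(mass, index=proteins),
    )


@pytest.fixture(scope="session")
def sim_experiment():
    """One moderately sized simulated experiment shared across tests."""
    cfg = SimConfig(n_proteins=800, seed=1)
    q, truth = simulate_eric_experiment(cfg)
    return cfg, q, truth


@pytest.fixture(scope="session")
def fitted_eric(sim_experiment):
    """Fitted poly(A) capture enrichment results on the shared simulation."""
    _, q, truth = sim_experiment
    eric = q.subset_samples([s.sample_id for s in q.samples if s.assay == "eric"])
    res = EnrichmentModel.from_quant(eric).fit()
    return q, truth, res
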