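import numpy as np
import pandas as pd
import pytest

from methylmark import GeneratorConfig, MethylationDataset, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One generated dataset (default study conditions) shared across tests."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def quiet_dataset():
    """Low-noise dataset (~0.02 beta-scale noise) for recovery checks."""
    return generate_dataset(GeneratorConfig(seed=2, noise_sd=0.08, batch_shift_sd=0.0,
                                            batch_scale_sd=0.0))


def make_dataset(beta: np.ndarray, *, group=None, chromosome=None, design_type=None,
                 snp=None, cross=None, detection_p=None, bead_count=None,
                 batch=None, sex=None) -> MethylationDataset:
    """Assemble a MethylationDataset from plain arrays, filling sane defaults."""
    beta = np.asarray(beta, float)
    p, n = beta.shape
    probes = pd.Index([f"cg{i:05d}" for i in range(p)], name="probe_id")
    samp = pd.Index([f"S{j:03d}" for j in range(n)], name="sample_id")
    group = list(group) if group is not None else ["case"] * (n // 2) + ["control"] * (n - n // 2)
    samples = pd.DataFrame(
        {
            "group": group,
            "age": np.linspace(20, 40, n),
            "sex": list(sex) if sex is not None else ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "batch_id": list(batch) if batch is not None else ["B1"] * n,
            "iq": np.full(n, 105.0),
            "ados_total": np.where(np.asarray(group) == "case", 7.0, 1.5),
            "assq_total": np.where(np.asarray(group) == "case", 28.6, 6.1),
        },
        index=samp,
    )
    annotation = pd.DataFrame(
        {
            "chromosome": list(chromosome) if chromosome is not None else ["1"] * p,
            "design_type": list(design_type) if design_type is not None else ["II"] * p,
            "snp_flag": list(snp) if snp is not None else [0] * p,
            "cross_reactive_flag": list(cross) if cross is not None else [0] * p,
            "gene_symbol": [""] * p,
        },
        index=probes,
    )
    det = detection_p if detection_p is not None else np.full((p, n), 0.001)
    beads = bead_count if bead_count is not None else np.full((p, n), 12, int)
    return MethylationDataset(
        beta=pd.DataFrame(beta, index=probes, columns=samp),
        detection_p=pd.DataFrame(np.asarray(det, float), index=probes, columns=samp),
        bead_count=pd.DataFrame(np.asarray(beads, int), index=probes, columns=samp),
        annotation=annotation,
        samples=samples,
    )
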