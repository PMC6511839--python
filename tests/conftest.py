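import numpy as np
import pandas as pd
import pytest

from onecell_dge import counting, simulate
from onecell_dge.barcodes import design_indexes


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small error-free simulation run end-to-end once per session."""
    from onecell_dge import pipeline
    d = tmp_path_factory.mktemp("smallsim")
    cfg = simulate.SimConfig(n_genes=30, n_cells=4, expression_mu=np.log(10),
                             p_dup=0.5, seed=11)
    ref = simulate.make_reference(cfg)
    ref_paths = ref.write(d)
    fq_paths, truth = simulate.simulate_cells(cfg, ref, d)
    t2g = counting.TranscriptGeneMap.from_tsv(ref_paths["t2g"])
    matrix, report, assignments = pipeline.run_pipeline(
        fq_paths["read1"], fq_paths["index"], truth.index_set,
        ref_paths["fasta"], t2g, d / "work", seed=3)
    return {"cfg": cfg, "ref": ref, "ref_paths": ref_paths,
            "fq_paths": fq_paths, "truth": truth, "t2g": t2g,
            "matrix": matrix, "report": report, "assignments": assignments,
            "dir": d}


@pytest.fixture(scope="session")
def barcode_set_103():
    return design_indexes(103, length=8, min_distance=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nb_counts():
    """Genes × samples NB counts with two groups and no true differences."""
    rng = np.random.default_rng(7)
    mu = rng.lognormal(3.0, 1.0, size=300)
    phi = 0.1
    r = 1 / phi
    counts = np.vstack([rng.negative_binomial(r, r / (r + m), size=6) for m in mu])
    return pd.DataFrame(counts, index=[f"g{i:03d}" for i in range(300)],
                        columns=[f"s{j}" for j in range(6)])
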