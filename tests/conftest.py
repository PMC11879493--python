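import numpy as np
import pytest

from shadenet import simdata

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_map():
    return simdata.make_map(2, 5, 100.0, (1, 3), seed=11)


@pytest.fixture(scope="session")
def small_rils(small_map):
    return simdata.simulate_rils(small_map, 60, 6, seed=12)


@pytest.fixture(scope="session")
def gwas_population():
    """A 250-line panel with one planted QTL per chromosome, reused by the
    association tests."""
    gmap = simdata.make_map(10, 10, 120.0, 1, seed=21)
    rils = simdata.simulate_rils(gmap, 250, 6, seed=22)
    rng = np.random.default_rng(23)
    r2 = [0.02, 0.05, 0.08, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10]
    genes = []
    for c in range(10):
        ids = [l.gene_id for l in gmap.loci if l.chrom_id == f"chr{c + 1:02d}"]
        genes.append(str(rng.choice(ids)))
    qtl = [simdata.QTLEffect(g, float(np.sqrt(v)), np.zeros(3)) for g, v in zip(genes, r2)]
    arch = simdata.TraitArchitecture(qtl=qtl, mu=1.6, h2_main=0.85, h2_gei=0.0, n_env=3, n_rep=3)
    return {"gmap": gmap, "rils": rils, "arch": arch, "qtl_genes": genes, "qtl_r2": dict(zip(genes, r2))}
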